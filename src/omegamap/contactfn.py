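"""Continuous, orientation- and sequence-dependent residue contact function.

A contact between residues i and j is scored in [0, 1] instead of with a
binary distance threshold.  The score depends on

* the amino-acid identities of the pair,
* the *range* (sequence separation |i - j|, binned 1, 2, 3, 4, long),
* the Euclidean distance d between interaction sites (CB, CA for glycine),
* for ranges 2-4, the relative rotation between the residues' local frames.

Per (identity pair, range) class, reference structures define a *Euclidean
contact interval* [d_lo, d_hi] — the fuzzy band over which the contact
score ramps from 1 down to 0 — as the shortest interval around the first
inter-residue distance density maximum holding a fixed fraction of the
short-distance density mass.  Short-range classes additionally carry a
*preferred rotation* (chordal mean of observed relative rotations within
the interval) and a tolerance ``theta_max``.

The raw distance is first mapped to a *relative pose distance*

    d' = d - alpha(d) * s(theta),      s(theta) = max(0, 1 - theta/theta_max)

where ``alpha(d) = alpha_max * c(d)`` fades smoothly to zero past d_hi, so
the orientation bonus vanishes for distant pairs and for long-range or
adjacent pairs (d' = d exactly there).  The contact value is then the
cosine ramp

    omega(d') = 1                                   d' <= d_lo
              = (1 + cos(pi (d'-d_lo)/(d_hi-d_lo)))/2   d_lo < d' < d_hi
              = 0                                   d' >= d_hi

which is continuous, strictly decreasing across the interval, and keeps
omega in [0, 1] everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .io import Conformation, Ensemble, build_frames

#: range classes; orientation terms exist only for 2, 3, 4
RANGE_CLASSES = (1, 2, 3, 4, "long")
ORIENTED_RANGES = frozenset({2, 3, 4})

#: wildcard amino-acid code used by pooled backoff entries
ANY = "ANY"


def range_class(separation: int):
    """Bin a sequence separation |i - j| into 1, 2, 3, 4 or ``"long"``."""
    if separation < 1:
        raise ValueError("separation must be >= 1")
    return separation if separation <= 4 else "long"


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-last, scipy convention)
# ---------------------------------------------------------------------------

def quat_angle(q1: np.ndarray, q2: np.ndarray) -> float:
    """Geodesic angle (rad) between two unit quaternions in SO(3)."""
    dot = abs(float(np.dot(q1, q2)))
    return 2.0 * np.arccos(min(dot, 1.0))


def _conjugate(q: np.ndarray) -> np.ndarray:
    out = -np.asarray(q, dtype=float)
    out[3] = -out[3]
    return out


def mean_quaternion(quats: np.ndarray) -> np.ndarray:
    """Chordal L2 mean of unit quaternions (largest eigenvector of the
    outer-product sum; delegated to scipy's rotation mean)."""
    return Rotation.mean(Rotation.from_quat(np.asarray(quats))).as_quat()


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PairContactParams:
    """Contact parameters of one (identity pair, range) class.

    ``preferred_rotation`` / ``theta_max`` are None for range 1 and long.
    ``alpha_max`` bounds the orientation-induced distance reduction and
    never exceeds ``d_lo`` so the pose distance stays non-negative.
    """

    d_lo: float
    d_hi: float
    preferred_rotation: np.ndarray | None = None
    theta_max: float | None = None
    alpha_max: float = 0.0
    support_count: int = 0

    def __post_init__(self):
        if not 0.0 < self.d_lo < self.d_hi <= 20.0:
            raise ValueError(f"invalid contact interval [{self.d_lo}, {self.d_hi}]")
        if self.preferred_rotation is not None:
            self.preferred_rotation = np.asarray(self.preferred_rotation, float)
            if self.theta_max is None or not 0.0 < self.theta_max <= np.pi:
                raise ValueError(f"invalid theta_max {self.theta_max}")
        if not 0.0 <= self.alpha_max <= self.d_lo:
            raise ValueError(f"alpha_max {self.alpha_max} outside [0, d_lo]")

    def swapped(self) -> "PairContactParams":
        """Parameters of the identity-swapped pair: same interval, inverse
        preferred rotation."""
        q = None if self.preferred_rotation is None else _conjugate(self.preferred_rotation)
        return PairContactParams(self.d_lo, self.d_hi, q, self.theta_max,
                                 self.alpha_max, self.support_count)


@dataclass
class RelativePose:
    """Distance plus angular deviation from the preferred rotation."""

    d: float
    theta: float | None = None


def _canonical_key(aa_i: str, aa_j: str, rng) -> tuple[tuple[str, str, object], bool]:
    """Alphabetically ordered lookup key and whether the pair was swapped."""
    if aa_j < aa_i:
        return (aa_j, aa_i, rng), True
    return (aa_i, aa_j, rng), False


@dataclass
class ContactParameterTable:
    """Per-class contact parameters with pooled (ANY, ANY, range) backoff.

    Entries are stored under alphabetically ordered identity pairs; a query
    for the swapped pair returns the same interval with the inverse
    preferred rotation, so the table is exactly swap-symmetric.
    """

    entries: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def lookup(self, aa_i: str, aa_j: str, rng) -> PairContactParams:
        """Resolve (aa_i, aa_j, range), backing off to the pooled entry."""
        key, swapped = _canonical_key(aa_i, aa_j, rng)
        params = self.entries.get(key)
        if params is None:
            params = self.entries.get((ANY, ANY, rng))
            if params is None:
                raise KeyError(f"no entry or backoff for range {rng!r}")
            swapped = False  # pooled entries are identity-symmetric
        return params.swapped() if swapped else params

    def to_json(self, path: str | Path | None = None) -> str:
        recs = []
        for (a, b, rng), p in sorted(self.entries.items(), key=lambda kv: str(kv[0])):
            rec = asdict(p)
            rec["preferred_rotation"] = (
                None if p.preferred_rotation is None
                else [float(x) for x in p.preferred_rotation]
            )
            rec.update(aa_i=a, aa_j=b, range=str(rng))
            recs.append(rec)
        text = json.dumps({"metadata": self.metadata, "entries": recs}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ContactParameterTable":
        text = Path(source).read_text() if Path(str(source)[:200]).is_file() else str(source)
        doc = json.loads(text)
        table = cls(metadata=doc.get("metadata", {}))
        for rec in doc["entries"]:
            rng = rec["range"] if rec["range"] == "long" else int(rec["range"])
            table.entries[(rec["aa_i"], rec["aa_j"], rng)] = PairContactParams(
                d_lo=rec["d_lo"], d_hi=rec["d_hi"],
                preferred_rotation=rec["preferred_rotation"],
                theta_max=rec["theta_max"], alpha_max=rec["alpha_max"],
                support_count=rec["support_count"],
            )
        return table


# ---------------------------------------------------------------------------
# the contact function itself
# ---------------------------------------------------------------------------

def relative_pose(rotation_i: np.ndarray, rotation_j: np.ndarray, d: float,
                  params: PairContactParams) -> RelativePose:
    """Angular deviation of the observed relative rotation from the class's
    preferred one.  ``theta`` is None when the class has no orientation term
    (range 1 or long)."""
    if params.preferred_rotation is None:
        return RelativePose(d=d)
    r_rel = rotation_i @ rotation_j.T
    r_pref = Rotation.from_quat(params.preferred_rotation).as_matrix()
    cos = (np.trace(r_pref.T @ r_rel) - 1.0) / 2.0
    return RelativePose(d=d, theta=float(np.arccos(np.clip(cos, -1.0, 1.0))))


def _distance_fade(d, d_hi, fade_width: float = 2.0):
    """Smooth cutoff c(d): 1 below d_hi, cosine fade to 0 over fade_width."""
    t = np.clip((d - d_hi) / fade_width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def pose_distance(pose: RelativePose, params: PairContactParams, rng) -> float:
    """Relative pose distance d' in [d - alpha_max, d].

    Equals the raw Euclidean distance exactly for range 1 and long-range
    pairs, for orientations at or beyond ``theta_max``, and for distances
    past the faded contact interval.
    """
    if rng not in ORIENTED_RANGES or pose.theta is None:
        return pose.d
    affinity = max(0.0, 1.0 - pose.theta / params.theta_max)
    alpha = params.alpha_max * _distance_fade(pose.d, params.d_hi)
    return pose.d - alpha * affinity


def contact_value(d_prime: float, params: PairContactParams):
    """Cosine-ramp contact score omega(d') in [0, 1]."""
    d_prime = np.asarray(d_prime, dtype=float)
    t = np.clip((d_prime - params.d_lo) / (params.d_hi - params.d_lo), 0.0, 1.0)
    omega = 0.5 * (1.0 + np.cos(np.pi * t))
    return float(omega) if omega.ndim == 0 else omega


def pair_contact(conf: Conformation, i: int, j: int,
                 table: ContactParameterTable) -> float:
    """Contact value of residues ``i < j`` (1-based) in one conformation."""
    if not i < j:
        raise IndexError("pair_contact requires i < j")
    from .io import interaction_distance

    rng = range_class(j - i)
    params = table.lookup(conf.sequence[i - 1], conf.sequence[j - 1], rng)
    d = interaction_distance(conf, i, j)
    if rng in ORIENTED_RANGES:
        _, rotations = build_frames(conf)
        pose = relative_pose(rotations[i - 1], rotations[j - 1], d, params)
    else:
        pose = RelativePose(d=d)
    return contact_value(pose_distance(pose, params, rng), params)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class EstimationSettings:
    """Knobs of the reference-based parameter estimation.

    mass_fraction
        Fraction of the sub-``peak_below`` density mass the contact
        interval must hold (the "fuzzy boundary" width).
    theta_percentile
        Percentile of in-interval angular deviations used as theta_max.
    min_support
        Classes with fewer informative observations back off to the
        pooled (ANY, ANY, range) entry.
    """

    min_support: int = 200
    mass_fraction: float = 0.6
    theta_percentile: float = 75.0
    max_distance: float = 14.0
    peak_below: float = 12.0
    grid_step: float = 0.02
    bandwidth: str | float = "silverman"
    alpha_fraction: float = 0.5  # alpha_max = min(d_lo, alpha_fraction*(d_hi-d_lo))


class EstimationError(RuntimeError):
    """Raised when reference data cannot support parameter estimation."""


def _contact_interval(distances: np.ndarray, settings: EstimationSettings):
    """[d_lo, d_hi] = shortest interval around the first density maximum
    below ``peak_below`` holding ``mass_fraction`` of the sub-peak mass."""
    d = np.asarray(distances, float)
    d = d[(d > 0) & (d <= settings.max_distance)]
    if len(d) == 0:
        raise EstimationError("no informative distances below the cutoff")
    if len(d) < 5 or np.ptp(d) < 2.0 * settings.grid_step:
        # degenerate support (few or near-identical observations): KDE is
        # ill-conditioned, fall back to a tight band around them
        center = float(np.mean(d))
        return max(0.05, center - 0.25), center + 0.25
    kde = gaussian_kde(d, bw_method=settings.bandwidth)
    grid = np.arange(max(settings.grid_step, d.min() - 1.0),
                     settings.max_distance + settings.grid_step,
                     settings.grid_step)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=0.01 * dens.max())
    peaks = [p for p in peaks if grid[p] < settings.peak_below]
    if not peaks:
        interior = np.argmax(dens)
        if grid[interior] >= settings.peak_below or interior in (0, len(grid) - 1):
            raise EstimationError(
                f"no density maximum below {settings.peak_below} A"
            )
        peaks = [interior]
    peak = peaks[0]

    sub = grid < settings.peak_below
    target = settings.mass_fraction * dens[sub].sum()
    lo = hi = peak
    mass = dens[peak]
    while mass < target and (lo > 0 or hi < len(grid) - 1):
        left = dens[lo - 1] if lo > 0 else -np.inf
        right = dens[hi + 1] if hi < len(grid) - 1 else -np.inf
        if left >= right:
            lo -= 1
            mass += dens[lo]
        else:
            hi += 1
            mass += dens[hi]
    return float(grid[lo]), float(grid[hi])


def estimate_pair_params(
    distances: np.ndarray,
    quaternions: np.ndarray | None = None,
    settings: EstimationSettings | None = None,
) -> PairContactParams:
    """Estimate one class's parameters from raw reference observations.

    Parameters
    ----------
    distances : array
        Interaction-site distances (Å) of all reference pairs in the class.
    quaternions : array, shape (n, 4), optional
        Relative rotations frame_i -> frame_j (scalar-last quaternions) of
        the same observations; required for oriented (short-range) classes.
    """
    settings = settings or EstimationSettings()
    d_lo, d_hi = _contact_interval(distances, settings)
    preferred = theta_max = None
    if quaternions is not None:
        distances = np.asarray(distances, float)
        quaternions = np.asarray(quaternions, float)
        in_int = distances <= d_hi
        if in_int.sum() >= 2:
            q_in = quaternions[in_int]
            preferred = mean_quaternion(q_in)
            dev = 2.0 * np.arccos(np.minimum(np.abs(q_in @ preferred), 1.0))
            theta_max = float(np.percentile(dev, settings.theta_percentile))
            theta_max = float(np.clip(theta_max, 1e-3, np.pi))
    alpha_max = (min(d_lo, settings.alpha_fraction * (d_hi - d_lo))
                 if preferred is not None else 0.0)
    n_support = int(np.sum(np.asarray(distances, float) <= settings.max_distance))
    return PairContactParams(d_lo=d_lo, d_hi=d_hi, preferred_rotation=preferred,
                             theta_max=theta_max, alpha_max=alpha_max,
                             support_count=n_support)


def _iter_reference_conformations(reference):
    if isinstance(reference, (Conformation, Ensemble)):
        reference = [reference]
    for item in reference:
        if isinstance(item, Ensemble):
            yield from item.conformations
        else:
            yield item


def collect_observations(reference, max_distance: float = 14.0):
    """Scan reference structures into per-class observation arrays.

    Returns
    -------
    dict
        ``(aa_i, aa_j, range) -> (distances, quaternions | None)`` with
        identity pairs in canonical (alphabetical) order; includes the
        pooled ``(ANY, ANY, range)`` classes.
    """
    dist_acc: dict = {}
    quat_acc: dict = {}

    def push(key, d, q):
        dist_acc.setdefault(key, []).append(d)
        if q is not None:
            quat_acc.setdefault(key, []).append(q)

    for conf in _iter_reference_conformations(reference):
        L = conf.n_residues
        sites = conf.interaction_sites
        diff = sites[None, :, :] - sites[:, None, :]
        dmat = np.linalg.norm(diff, axis=-1)
        _, rotations = build_frames(conf)
        for i in range(L - 1):
            for j in range(i + 1, L):
                d = dmat[i, j]
                if d > max_distance:
                    continue
                rng = range_class(j - i)
                a, b = conf.sequence[i], conf.sequence[j]
                q = None
                if rng in ORIENTED_RANGES:
                    r_rel = rotations[i] @ rotations[j].T
                    q = Rotation.from_matrix(r_rel).as_quat()
                    if b < a:
                        q = _conjugate(q)
                key, _ = _canonical_key(a, b, rng)
                push(key, d, q)
                push((ANY, ANY, rng), d, q)
    out = {}
    for key, ds in dist_acc.items():
        qs = np.array(quat_acc[key]) if key in quat_acc else None
        out[key] = (np.array(ds), qs)
    return out


def estimate_parameters(reference, settings: EstimationSettings | None = None
                        ) -> ContactParameterTable:
    """Estimate a full contact-parameter table from reference structures.

    Every (identity pair, range) class with at least ``min_support``
    informative observations gets its own entry; all others resolve through
    the pooled (ANY, ANY, range) entries, which are always estimated and
    whose absence of a short-distance density maximum is a hard error.
    """
    settings = settings or EstimationSettings()
    obs = collect_observations(reference, max_distance=settings.max_distance)
    if not obs:
        raise EstimationError("empty reference set")
    table = ContactParameterTable(metadata={
        "min_support": settings.min_support,
        "mass_fraction": settings.mass_fraction,
        "theta_percentile": settings.theta_percentile,
    })
    for rng in RANGE_CLASSES:
        key = (ANY, ANY, rng)
        if key not in obs:
            raise EstimationError(f"no reference observations for range {rng!r}")
        ds, qs = obs[key]
        table.entries[key] = estimate_pair_params(ds, qs, settings)
    for key, (ds, qs) in obs.items():
        if key[0] == ANY:
            continue
        if len(ds) >= settings.min_support:
            try:
                table.entries[key] = estimate_pair_params(ds, qs, settings)
            except EstimationError:
                continue  # class backs off to the pooled entry
    return table


class ContactParameterEstimator:
    """Scikit-learn style estimator for contact-parameter tables.

    ``fit(X)`` with X a list of reference :class:`~omegamap.io.Conformation`
    or :class:`~omegamap.io.Ensemble` objects estimates ``table_``.
    """

    def __init__(self, min_support: int = 200, mass_fraction: float = 0.6,
                 theta_percentile: float = 75.0):
        self.min_support = min_support
        self.mass_fraction = mass_fraction
        self.theta_percentile = theta_percentile

    def get_params(self, deep: bool = True) -> dict:
        return {"min_support": self.min_support,
                "mass_fraction": self.mass_fraction,
                "theta_percentile": self.theta_percentile}

    def set_params(self, **params) -> "ContactParameterEstimator":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "ContactParameterEstimator":
        settings = EstimationSettings(min_support=self.min_support,
                                      mass_fraction=self.mass_fraction,
                                      theta_percentile=self.theta_percentile)
        self.table_ = estimate_parameters(X, settings)
        return self
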