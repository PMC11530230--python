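"""Per-conformation featurization of an ensemble.

Every conformation of a length-L ensemble is described by a vector over
all L(L-1)/2 residue pairs in lexicographic order (1,2), (1,3), ...,
(L-1,L), giving an n x L(L-1)/2 feature matrix.  Four featurizations are
provided:

omega
    the continuous contact function (identity-, range-, distance- and
    orientation-dependent) — the method's native representation;
distance
    raw CB-CB Euclidean distances (CA for glycine), the classical
    global-shape baseline;
lj
    summed inter-residue 12-6 Lennard-Jones energies over backbone heavy
    atoms, truncated and shifted at 10 Å;
binary
    not a matrix but the naive ensemble-average contact probability map
    at a hard distance threshold (8 Å default), for contrast plots.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .contactfn import (ContactParameterTable, ORIENTED_RANGES, _distance_fade,
                        range_class)
from .io import BACKBONE_ATOMS, Conformation, Ensemble, build_frames

FEATURE_KINDS = ("omega", "distance", "lj")


def pair_columns(L: int) -> list[tuple[int, int]]:
    """Lexicographic residue-pair order (1-based): (1,2), (1,3), ..., (L-1,L)."""
    return [(i, j) for i in range(1, L) for j in range(i + 1, L + 1)]


@dataclass
class FeatureMatrix:
    """n x L(L-1)/2 matrix of per-pair features, one row per conformation."""

    values: np.ndarray
    column_index: list[tuple[int, int]]
    feature_kind: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_conformations(self) -> int:
        return self.values.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        L = self.n_residues
        if self.values.shape[1] != L * (L - 1) // 2:
            raise ValueError(
                f"column count {self.values.shape[1]} != L(L-1)/2 = {L * (L - 1) // 2}"
            )
        if self.feature_kind == "omega":
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("omega features must lie in [0, 1]")
        elif self.feature_kind == "distance":
            if (self.values <= 0).any():
                raise ValueError("distances must be positive")

    def row_as_map(self, k: int) -> np.ndarray:
        """One row reshaped to a symmetric L x L matrix with zero diagonal."""
        return vector_to_map(self.values[k], self.n_residues)

    def save(self, path) -> None:
        """Persist as compressed binary plus a JSON header sidecar."""
        np.savez_compressed(path, values=self.values)
        header = {
            "feature_kind": self.feature_kind,
            "sequence": self.sequence,
            "column_index": self.column_index,
            "metadata": self.metadata,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(header, fh)


def vector_to_map(vector: np.ndarray, L: int) -> np.ndarray:
    """Condensed pair vector -> symmetric L x L matrix, zero diagonal."""
    out = np.zeros((L, L))
    iu = np.triu_indices(L, k=1)
    out[iu] = vector
    return out + out.T


# ---------------------------------------------------------------------------
# omega featurization (vectorized over pairs)
# ---------------------------------------------------------------------------

class _OmegaColumns:
    """Per-column contact parameters resolved once for a sequence."""

    def __init__(self, sequence: str, table: ContactParameterTable):
        L = len(sequence)
        cols = pair_columns(L)
        P = len(cols)
        self.columns = cols
        self.d_lo = np.empty(P)
        self.d_hi = np.empty(P)
        self.alpha_max = np.zeros(P)
        self.theta_max = np.ones(P)
        self.oriented = np.zeros(P, dtype=bool)
        pref = np.zeros((P, 3, 3))
        self.i_idx = np.array([i - 1 for i, _ in cols])
        self.j_idx = np.array([j - 1 for _, j in cols])
        for c, (i, j) in enumerate(cols):
            rng = range_class(j - i)
            p = table.lookup(sequence[i - 1], sequence[j - 1], rng)
            self.d_lo[c] = p.d_lo
            self.d_hi[c] = p.d_hi
            if rng in ORIENTED_RANGES and p.preferred_rotation is not None:
                self.oriented[c] = True
                self.alpha_max[c] = p.alpha_max
                self.theta_max[c] = p.theta_max
                pref[c] = Rotation.from_quat(p.preferred_rotation).as_matrix()
        self.pref = pref[self.oriented]

    def omega_row(self, conf: Conformation) -> np.ndarray:
        d = pdist(conf.interaction_sites)  # condensed == lexicographic order
        d_prime = d.copy()
        if self.oriented.any():
            _, rot = build_frames(conf)
            sel = self.oriented
            r_rel = np.einsum("nab,ncb->nac", rot[self.i_idx[sel]], rot[self.j_idx[sel]])
            cos = (np.einsum("nab,nab->n", self.pref, r_rel) - 1.0) / 2.0
            theta = np.arccos(np.clip(cos, -1.0, 1.0))
            affinity = np.maximum(0.0, 1.0 - theta / self.theta_max[sel])
            alpha = self.alpha_max[sel] * _distance_fade(d[sel], self.d_hi[sel])
            d_prime[sel] = d[sel] - alpha * affinity
        t = np.clip((d_prime - self.d_lo) / (self.d_hi - self.d_lo), 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))


def featurize_omega(ens: Ensemble, table: ContactParameterTable) -> FeatureMatrix:
    """Contact-function feature matrix: row k, column (i,j) holds the
    contact value omega_ij of conformation k."""
    cols = _OmegaColumns(ens.sequence, table)
    values = np.empty((ens.n_conformations, len(cols.columns)))
    for k, conf in enumerate(ens.conformations):
        values[k] = cols.omega_row(conf)
    return FeatureMatrix(values, cols.columns, "omega", ens.sequence)


def featurize_distance(ens: Ensemble) -> FeatureMatrix:
    """Pairwise interaction-site (CB; CA for glycine) distance matrix."""
    L = ens.n_residues
    values = np.empty((ens.n_conformations, L * (L - 1) // 2))
    for k, conf in enumerate(ens.conformations):
        values[k] = pdist(conf.interaction_sites)
    return FeatureMatrix(values, pair_columns(L), "distance", ens.sequence)


# ---------------------------------------------------------------------------
# Lennard-Jones featurization
# ---------------------------------------------------------------------------

#: generic heavy-atom Lennard-Jones classes: sigma (A), epsilon (kcal/mol)
DEFAULT_LJ_CLASSES = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
}

_ATOM_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def featurize_lj(ens: Ensemble, lj_params: dict | None = None,
                 cutoff: float = 10.0) -> FeatureMatrix:
    """Summed inter-residue 12-6 Lennard-Jones energies over heavy atoms.

    Pair terms use Lorentz-Berthelot combination and are truncated and
    shifted to zero at ``cutoff``; atoms of unknown class fall back to
    carbon with a warning.
    """
    lj_params = lj_params or DEFAULT_LJ_CLASSES
    L = ens.n_residues
    cols = pair_columns(L)
    col_of = {pair: c for c, pair in enumerate(cols)}

    # flat atom tables (identical across conformations)
    template = ens.conformations[0]
    res_idx, sigma, eps, slots = [], [], [], []
    for r in range(L):
        for s, name in enumerate(BACKBONE_ATOMS):
            if not np.isfinite(template.coords[r, s]).all():
                continue
            element = _ATOM_ELEMENT[name]
            if element not in lj_params:
                warnings.warn(f"unknown LJ class {element!r}; using C", stacklevel=2)
                element = "C"
            sg, ep = lj_params[element]
            res_idx.append(r)
            sigma.append(sg)
            eps.append(ep)
            slots.append(s)
    res_idx = np.array(res_idx)
    sigma = np.array(sigma)
    eps = np.array(eps)
    sig_ab = 0.5 * (sigma[:, None] + sigma[None, :])
    eps_ab = np.sqrt(eps[:, None] * eps[None, :])
    shift = 4.0 * eps_ab * ((sig_ab / cutoff) ** 12 - (sig_ab / cutoff) ** 6)
    different_res = res_idx[:, None] != res_idx[None, :]

    values = np.zeros((ens.n_conformations, len(cols)))
    for k, conf in enumerate(ens.conformations):
        xyz = conf.coords[res_idx, slots]
        diff = xyz[:, None, :] - xyz[None, :, :]
        r = np.sqrt((diff ** 2).sum(-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = (sig_ab / r) ** 6
            v = 4.0 * eps_ab * (sr6 ** 2 - sr6) - shift
        mask = different_res & (r < cutoff) & (r > 0)
        v = np.where(mask, v, 0.0)
        row = values[k]
        a_idx, b_idx = np.nonzero(np.triu(mask, k=1))
        for a, b in zip(a_idx, b_idx):
            ri, rj = res_idx[a], res_idx[b]
            if ri != rj:
                pair = (ri + 1, rj + 1) if ri < rj else (rj + 1, ri + 1)
                row[col_of[pair]] += v[a, b]
    return FeatureMatrix(values, cols, "lj", ens.sequence)


def mean_binary_contact_map(ens: Ensemble, threshold: float = 8.0) -> np.ndarray:
    """Naive contact probability map: fraction of conformations whose
    interaction-site distance is below ``threshold`` (Å), per pair.
    Symmetric L x L with zero diagonal."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = ens.n_residues
    counts = np.zeros(L * (L - 1) // 2)
    for conf in ens.conformations:
        counts += pdist(conf.interaction_sites) <= threshold
    return vector_to_map(counts / ens.n_conformations, L)


# ---------------------------------------------------------------------------
# sklearn-style transformer surface
# ---------------------------------------------------------------------------

class _BaseFeaturizer:
    """Transformer mapping an :class:`~omegamap.io.Ensemble` to the feature
    array; ``feature_matrix()`` returns the annotated container."""

    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Ensemble, y=None):
        return self

    def transform(self, X: Ensemble) -> np.ndarray:
        return self.feature_matrix(X).values

    def fit_transform(self, X: Ensemble, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)


class OmegaFeaturizer(_BaseFeaturizer):
    """Contact-function featurizer bound to a parameter table."""

    _param_names = ("table",)

    def __init__(self, table: ContactParameterTable):
        self.table = table

    def feature_matrix(self, X: Ensemble) -> FeatureMatrix:
        return featurize_omega(X, self.table)


class DistanceFeaturizer(_BaseFeaturizer):
    """Pairwise-distance featurizer (global-shape baseline)."""

    def feature_matrix(self, X: Ensemble) -> FeatureMatrix:
        return featurize_distance(X)


class LennardJonesFeaturizer(_BaseFeaturizer):
    """Inter-residue Lennard-Jones energy featurizer."""

    _param_names = ("lj_params", "cutoff")

    def __init__(self, lj_params: dict | None = None, cutoff: float = 10.0):
        self.lj_params = lj_params
        self.cutoff = cutoff

    def feature_matrix(self, X: Ensemble) -> FeatureMatrix:
        return featurize_lj(X, self.lj_params, self.cutoff)
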