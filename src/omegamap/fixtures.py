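"""Synthetic conformational ensembles with known family structure.

Chains are built from backbone dihedrals with ideal bond geometry
(N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, trans peptide bonds), so every
generated conformation passes the backbone invariants and all ground-truth
family labels are exact.  Families emulate the motif classes seen in
disordered-ensemble analyses: random coil (three-basin Ramachandran
mixture), local helix or turn segments on a coil background, transient
long-range contacts closed by rejection sampling, and beta hairpins.

The reference-set generator provides small folded-like chains (mixed
helix/strand/coil) so that contact-parameter estimation has genuine
distance density maxima and orientation modes at short ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Conformation, Ensemble

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0

#: canonical (phi, psi) in degrees
HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)
#: alternating pair applied across a turn segment (type-I-like)
TURN_PHI_PSI = ((-60.0, -30.0), (-90.0, 0.0))

#: hairpin template dihedrals, numerically tuned so the two arms satisfy
#: the antiparallel backbone H-bond registry (strand labels under the
#: Kabsch-Sander rules); synthetic values, not Ramachandran-canonical
HAIRPIN_STRAND1 = (-32.5, 99.0)
HAIRPIN_STRAND2 = (165.6, 82.8)
HAIRPIN_TURN = ((20.1, 53.9), (154.6, -22.8))

#: Ramachandran basins of the coil model: (phi, psi, weight)
COIL_BASINS = (
    (-135.0, 135.0, 0.45),   # beta / polyproline region
    (-60.0, -45.0, 0.45),    # alpha_R
    (60.0, 45.0, 0.10),      # alpha_L
)

FAMILY_KINDS = ("coil", "helix_segment", "turn_segment",
                "longrange_contact", "hairpin")


@dataclass
class FamilySpec:
    """One conformer family of a synthetic ensemble.

    segment
        1-based inclusive residue bounds of the structured motif
        (helix/turn/hairpin families).
    contact_pair
        1-based residue pair forced within ``contact_distance`` Å
        (longrange_contact and hairpin families).
    noise
        Gaussian jitter (rad) on the motif dihedrals.
    """

    kind: str
    count: int
    segment: tuple[int, int] | None = None
    contact_pair: tuple[int, int] | None = None
    noise: float = 0.10
    coil_noise: float = 0.30
    contact_distance: float = 6.0

    def __post_init__(self):
        if self.kind not in FAMILY_KINDS:
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


from math import cos, radians, sin, sqrt


def _place_atom(a, b, c, length, angle_deg, dihedral_deg):
    """Next atom position from three predecessors and internal coordinates
    (natural extension reference frame).  Scalar math: this sits in the
    innermost loop of chain construction and rejection sampling."""
    angle = radians(angle_deg)
    dihedral = radians(dihedral_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    ibc = 1.0 / sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * ibc, bcy * ibc, bcz * ibc
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inn = 1.0 / sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inn, ny * inn, nz * inn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -length * cos(angle)
    d1 = length * sin(angle) * cos(dihedral)
    d2 = length * sin(angle) * sin(dihedral)
    return np.array([
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    ])


def _cb_position(n, ca, c):
    """Ideal tetrahedral CB from backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_chain(dihedrals: Sequence[tuple[float, float]],
                sequence: str | None = None) -> Conformation:
    """Deterministically build a backbone from per-residue (phi, psi).

    Parameters
    ----------
    dihedrals : sequence of (phi, psi) in degrees, length L
        ``phi`` of residue 1 is unused; ``psi`` of residue L orients its
        carbonyl oxygen.
    sequence : str, optional
        One-letter sequence (poly-alanine by default).  Glycines get no CB.
    """
    L = len(dihedrals)
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length must match dihedral list")

    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # first residue in a canonical pose
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(L - 1):
        psi = dihedrals[i][1]
        N[i + 1] = _place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], BOND_N_CA,
                                ANGLE_C_N_CA, OMEGA_TRANS)
        phi = dihedrals[i + 1][0]
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C,
                               ANGLE_N_CA_C, phi)

    # carbonyl oxygens: anti-bisector of CA and next N in the peptide plane
    O = np.zeros((L, 3))
    virtual_n = _place_atom(N[L - 1], CA[L - 1], C[L - 1], BOND_C_N,
                            ANGLE_CA_C_N, dihedrals[L - 1][1])
    next_n = np.vstack([N[1:], virtual_n])
    for i in range(L):
        u = CA[i] - C[i]
        v = next_n[i] - C[i]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        w = -(u + v)
        O[i] = C[i] + BOND_C_O * w / np.linalg.norm(w)

    coords = np.full((L, 5, 3), np.nan)
    coords[:, 0] = N
    coords[:, 1] = CA
    coords[:, 2] = C
    coords[:, 3] = O
    for i in range(L):
        if sequence[i] != "G":
            coords[i, 4] = _cb_position(N[i], CA[i], C[i])
    return Conformation(sequence, coords)


def _coil_dihedrals(L, rng, noise_rad):
    weights = np.array([b[2] for b in COIL_BASINS])
    idx = rng.choice(len(COIL_BASINS), size=L, p=weights / weights.sum())
    noise_deg = np.degrees(noise_rad)
    out = []
    for i in range(L):
        phi0, psi0, _ = COIL_BASINS[idx[i]]
        out.append((phi0 + rng.normal(0, noise_deg),
                    psi0 + rng.normal(0, noise_deg)))
    return out


def _family_dihedrals(spec: FamilySpec, L, rng):
    dih = _coil_dihedrals(L, rng, spec.coil_noise)
    noise_deg = np.degrees(spec.noise)
    if spec.kind in ("helix_segment", "turn_segment"):
        if spec.segment is None:
            raise ValueError(f"{spec.kind} family requires a segment")
        lo, hi = spec.segment
        for r in range(lo - 1, hi):
            if spec.kind == "helix_segment":
                phi0, psi0 = HELIX_PHI_PSI
            else:
                phi0, psi0 = TURN_PHI_PSI[(r - (lo - 1)) % 2]
            dih[r] = (phi0 + rng.normal(0, noise_deg),
                      psi0 + rng.normal(0, noise_deg))
    elif spec.kind == "hairpin":
        if spec.segment is None:
            raise ValueError("hairpin family requires a segment")
        lo, hi = spec.segment
        mid = (lo + hi) // 2
        for r in range(lo - 1, hi):
            if r == mid - 1:
                phi0, psi0 = HAIRPIN_TURN[0]
            elif r == mid:
                phi0, psi0 = HAIRPIN_TURN[1]
            elif r < mid - 1:
                phi0, psi0 = HAIRPIN_STRAND1
            else:
                phi0, psi0 = HAIRPIN_STRAND2
            dih[r] = (phi0 + rng.normal(0, noise_deg),
                      psi0 + rng.normal(0, noise_deg))
    return dih


def _sample_family(spec: FamilySpec, sequence: str, rng,
                   max_tries: int = 200) -> list[Conformation]:
    L = len(sequence)
    needs_contact = spec.kind in ("longrange_contact", "hairpin")
    if needs_contact:
        if spec.contact_pair is None:
            if spec.kind == "hairpin" and spec.segment is not None:
                spec.contact_pair = spec.segment
            else:
                raise ValueError(f"{spec.kind} family requires contact_pair")
        i, j = spec.contact_pair
    confs = []
    for _ in range(spec.count):
        if not needs_contact:
            confs.append(build_chain(_family_dihedrals(spec, L, rng), sequence))
            continue
        # the site-site distance depends only on the dihedrals between the
        # contact pair, so rejection tests a partial build of that segment
        # (exact: flanking dihedrals are independent of the contact event)
        for attempt in range(max_tries):
            dih = _family_dihedrals(spec, L, rng)
            seg = build_chain(dih[i - 1:j], sequence[i - 1:j])
            sites = seg.interaction_sites
            if np.linalg.norm(sites[0] - sites[-1]) <= spec.contact_distance:
                confs.append(build_chain(dih, sequence))
                break
        else:
            raise RuntimeError(
                f"loop closure failed for {spec.kind} family: pair "
                f"{spec.contact_pair} not within {spec.contact_distance} A "
                f"after {max_tries} tries (noise={spec.noise}, "
                f"coil_noise={spec.coil_noise})"
            )
    return confs


def make_ensemble(specs: Sequence[FamilySpec], sequence: str,
                  seed: int = 0) -> tuple[Ensemble, np.ndarray]:
    """Generate a labeled synthetic ensemble as a mixture of families.

    Returns the ensemble (families concatenated in spec order) and the
    exact 0-based family label of every conformation.
    """
    if not specs:
        raise ValueError("at least one family spec is required")
    rng = np.random.default_rng(seed)
    confs: list[Conformation] = []
    labels: list[int] = []
    for f, spec in enumerate(specs):
        family = _sample_family(spec, sequence, rng)
        confs.extend(family)
        labels.extend([f] * len(family))
    ens = Ensemble(sequence, confs, provenance=[f"synthetic(seed={seed})"])
    ens.validate()
    return ens, np.array(labels)


#: fixed 27-residue test sequence (no proline; one glycine to exercise the
#: CA fallback of the interaction site)
CANONICAL_SEQUENCE = "MSTAYKELFDGNQVRHLIAWKESTDNF"


def canonical_family_specs(count: int = 1000) -> list[FamilySpec]:
    """The package's canonical 3-family benchmark mixture (L = 27).

    Three motif families on random-coil backgrounds, mirroring the motif
    classes transiently populated in disordered-ensemble analyses: a short
    C-terminal alpha-helix, a hairpin-stabilized long-range contact between
    the central and C-terminal regions, and a turn spanning residues 6-15.
    """
    return [
        FamilySpec("helix_segment", count=count, segment=(17, 25)),
        FamilySpec("hairpin", count=count, segment=(13, 25)),
        FamilySpec("turn_segment", count=count, segment=(6, 15)),
    ]


def rare_motif_specs(n_total: int = 3000, rare_fraction: float = 0.02,
                     segment: tuple[int, int] = (17, 25)) -> list[FamilySpec]:
    """A scarcely populated helix family diluted in random coil.

    Emulates the detection problem for transient structural elements:
    ``rare_fraction`` of the ensemble carries a helical segment, the rest
    is coil.
    """
    n_rare = max(1, int(round(rare_fraction * n_total)))
    return [
        FamilySpec("coil", count=n_total - n_rare),
        FamilySpec("helix_segment", count=n_rare, segment=segment),
    ]


_REF_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(L: int, rng) -> str:
    return "".join(rng.choice(list(_REF_AA), size=L))


def make_reference_set(n_structures: int, seed: int = 0,
                       length_range: tuple[int, int] = (24, 36)
                       ) -> list[Conformation]:
    """Toy stand-in for a curated structural database.

    Each chain is a random concatenation of helix, extended and coil runs
    with small dihedral jitter, yielding clustered short-range distances
    and orientation modes for parameter estimation.  Not publication-grade
    reference data.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    structures = []
    for _ in range(n_structures):
        L = int(rng.integers(*length_range))
        sequence = random_sequence(L, rng)
        dih = []
        r = 0
        while r < L:
            run = int(rng.integers(4, 12))
            # folded-domain-like composition: secondary structure dominates,
            # as in curated high-resolution structure databases
            motif = rng.choice(["helix", "extended", "coil", "hairpin"],
                               p=[0.5, 0.1, 0.1, 0.3])
            if motif == "hairpin":
                # packed antiparallel arms: the source of long-range
                # contact-distance density in the toy database
                run = min(int(rng.integers(10, 16)), L - r)
                if run < 8:
                    motif = "coil"
            for k in range(min(run, L - r)):
                if motif == "helix":
                    phi0, psi0 = HELIX_PHI_PSI
                    jitter = 5.0
                elif motif == "extended":
                    phi0, psi0 = EXTENDED_PHI_PSI
                    jitter = 8.0
                elif motif == "hairpin":
                    mid = run // 2
                    if k == mid - 1:
                        phi0, psi0 = HAIRPIN_TURN[0]
                    elif k == mid:
                        phi0, psi0 = HAIRPIN_TURN[1]
                    elif k < mid - 1:
                        phi0, psi0 = HAIRPIN_STRAND1
                    else:
                        phi0, psi0 = HAIRPIN_STRAND2
                    jitter = 2.5
                else:
                    basin = COIL_BASINS[rng.integers(0, 3)]
                    phi0, psi0, jitter = basin[0], basin[1], 12.0
                dih.append((phi0 + rng.normal(0, jitter),
                            psi0 + rng.normal(0, jitter)))
            r += run
        structures.append(build_chain(dih[:L], sequence))
    return structures
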