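"""Cluster-level characterization: weighted omega-contact maps and
structural descriptors.

Each cluster C_k of an n-conformation ensemble is summarized by the
*cluster-specific omega-contact map* — the mean of the contact-function
feature rows of its members, arranged as a symmetric L x L matrix — and
its occupancy weight p_k = |C_k| / n.  The weighted K-tuple of maps, plus
the fraction of noise conformations excluded from every cluster, is the
ensemble characterization.

Per-cluster descriptors complement the maps: secondary-structure
propensities from a native Kabsch-Sander (DSSP-style) assignment collapsed
to helix/strand/coil, the mass-weighted radius of gyration over available
heavy atoms, and the CA end-to-end distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import ClusterAssignment
from .featurize import FeatureMatrix, mean_binary_contact_map, vector_to_map
from .io import ATOM_MASSES, BACKBONE_ATOMS, Conformation, Ensemble, write_ensemble_pdb

SS_STATES = ("helix", "strand", "coil")

#: collapsed mapping of the 8 DSSP states
_COLLAPSE = {"H": "helix", "G": "helix", "I": "helix",
             "E": "strand", "B": "strand",
             "T": "coil", "S": "coil", "-": "coil"}


@dataclass
class OmegaContactMap:
    """Cluster-mean contact map with its occupancy weight."""

    values: np.ndarray          # symmetric L x L, zero diagonal
    weight: float               # p_k = |C_k| / n
    cluster_id: int
    occupancy: int              # |C_k|

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("contact map diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("contact map entries must lie in [0, 1]")


@dataclass
class ClusterDescriptors:
    """Structural summary of one cluster."""

    ss_propensity: np.ndarray   # (L, 3): fractions over (helix, strand, coil)
    rg_mean: float
    rg_sd: float
    end_to_end_mean: float


@dataclass
class EnsembleCharacterization:
    """The weighted family of cluster contact maps (plus descriptors)."""

    maps: list[OmegaContactMap]
    noise_fraction: float
    descriptors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.maps)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.maps])

    def validate(self) -> None:
        total = sum(m.occupancy for m in self.maps)
        n = self.provenance.get("n")
        if n is not None and abs(total / n + self.noise_fraction - 1.0) > 1e-9:
            raise ValueError("cluster weights and noise fraction must sum to 1")
        for m in self.maps:
            m.validate()


def cluster_contact_map(features: FeatureMatrix, members, n: int,
                        cluster_id: int = 0) -> OmegaContactMap:
    """Mean contact map of one cluster: entry (i,j) is the average omega_ij
    over member conformations; weight is |members| / n."""
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("empty member set")
    if features.feature_kind != "omega":
        raise ValueError(f"expected omega features, got {features.feature_kind!r}")
    mean_row = features.values[members].mean(axis=0)
    return OmegaContactMap(
        values=vector_to_map(mean_row, features.n_residues),
        weight=len(members) / n,
        cluster_id=cluster_id,
        occupancy=len(members),
    )


def characterize(features: FeatureMatrix,
                 assignment: ClusterAssignment) -> EnsembleCharacterization:
    """One weighted map per cluster, ordered by decreasing occupancy;
    cluster weights and the noise fraction partition the ensemble."""
    n = features.n_conformations
    if assignment.n != n:
        raise ValueError(
            f"features ({n}) and assignment ({assignment.n}) disagree on n"
        )
    maps = [cluster_contact_map(features, assignment.members(k), n, cluster_id=k)
            for k in range(1, assignment.K + 1)]
    maps.sort(key=lambda m: (-m.occupancy, m.cluster_id))
    char = EnsembleCharacterization(
        maps=maps,
        noise_fraction=assignment.noise_fraction,
        provenance={"n": n, "sequence": features.sequence},
    )
    char.validate()
    return char


# ---------------------------------------------------------------------------
# secondary structure (native Kabsch-Sander rules)
# ---------------------------------------------------------------------------

_KS_Q = 0.084 * 332.0  # kcal/mol * A, partial-charge coupling constant


def _amide_hydrogens(conf: Conformation) -> np.ndarray:
    """Reconstructed amide H positions, 1.01 A from N along the bisector
    opposite the preceding carbonyl; NaN for residue 1 and prolines."""
    L = conf.n_residues
    H = np.full((L, 3), np.nan)
    N, CA, C = conf.atom("N"), conf.atom("CA"), conf.atom("C")
    for i in range(1, L):
        if conf.sequence[i] == "P":
            continue  # proline nitrogen carries no amide hydrogen
        u = N[i] - C[i - 1]
        v = N[i] - CA[i]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        w = u + v
        H[i] = N[i] + 1.01 * w / np.linalg.norm(w)
    return H


def hydrogen_bond_energy(conf: Conformation) -> np.ndarray:
    """Kabsch-Sander electrostatic H-bond energies (kcal/mol).

    ``E[i, j]`` couples the carbonyl C=O of residue i (acceptor) with the
    amide N-H of residue j (donor):
    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).
    +inf marks impossible pairs (|i-j| < 2, missing H).
    """
    L = conf.n_residues
    C, O, N = conf.atom("C"), conf.atom("O"), conf.atom("N")
    H = _amide_hydrogens(conf)
    E = np.full((L, L), np.inf)
    for i in range(L):
        for j in range(L):
            if abs(i - j) < 2 or not np.isfinite(H[j]).all():
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                E[i, j] = -9.9  # atom clash: cap like classic DSSP
            else:
                E[i, j] = _KS_Q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return E


def secondary_structure(conf: Conformation) -> str:
    """Per-residue 8-state assignment (H/G/I/E/B/T/S/-) from backbone
    hydrogen-bond patterns; chains shorter than 5 are all coil."""
    L = conf.n_residues
    if L < 5:
        warnings.warn("chain shorter than 5 residues: all coil", stacklevel=2)
        return "-" * L
    hb = hydrogen_bond_energy(conf) < -0.5  # hb[i, j]: CO(i) <- NH(j)

    turn = {n: np.zeros(L, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(L - n):
            turn[n][i] = hb[i, i + n]

    ss = np.array(["-"] * L, dtype="<U1")

    def mark(idx, state):
        for i in idx:
            if ss[i] == "-":
                ss[i] = state

    # alpha helix: two consecutive 4-turns
    for i in range(1, L - 4):
        if turn[4][i - 1] and turn[4][i]:
            mark(range(i, i + 4), "H")

    # beta bridges and ladders
    bridges = []
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridges.append((i, j))
    bridge_set = set(bridges)
    for (i, j) in bridges:
        laddered = any(
            (i + di, j + dj) in bridge_set
            for di, dj in ((1, 1), (-1, -1), (1, -1), (-1, 1))
        )
        mark((i, j), "E" if laddered else "B")

    # 3-10 and pi helices (lower priority than H and strands)
    for i in range(1, L - 3):
        if turn[3][i - 1] and turn[3][i]:
            mark(range(i, i + 3), "G")
    for i in range(1, L - 5):
        if turn[5][i - 1] and turn[5][i]:
            mark(range(i, i + 5), "I")

    # hydrogen-bonded turns
    for n in (3, 4, 5):
        for i in range(L - n):
            if turn[n][i]:
                mark(range(i + 1, i + n), "T")

    # bends: CA-direction kink > 70 degrees
    ca = conf.ca
    for i in range(2, L - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70:
            mark([i], "S")

    return "".join(ss)


def collapse_ss(labels: str) -> list[str]:
    """8-state string -> per-residue helix/strand/coil."""
    return [_COLLAPSE[s] for s in labels]


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def radius_of_gyration(conf: Conformation) -> float:
    """Mass-weighted radius of gyration (Å) over available heavy atoms."""
    xyz, masses = [], []
    for slot, name in enumerate(BACKBONE_ATOMS):
        pos = conf.coords[:, slot, :]
        ok = np.isfinite(pos).all(axis=1)
        xyz.append(pos[ok])
        masses.append(np.full(ok.sum(), ATOM_MASSES[name]))
    xyz = np.concatenate(xyz)
    masses = np.concatenate(masses)
    com = (masses[:, None] * xyz).sum(0) / masses.sum()
    return float(np.sqrt((masses * ((xyz - com) ** 2).sum(1)).sum() / masses.sum()))


def end_to_end_distance(conf: Conformation) -> float:
    """CA(1)-CA(L) distance (Å)."""
    return float(np.linalg.norm(conf.ca[-1] - conf.ca[0]))


def cluster_descriptors(ens: Ensemble, members) -> ClusterDescriptors:
    """Secondary-structure propensities, radius of gyration and end-to-end
    distance averaged over the member conformations of one cluster."""
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("empty member set")
    L = ens.n_residues
    counts = np.zeros((L, len(SS_STATES)))
    rgs, e2e = [], []
    state_idx = {s: k for k, s in enumerate(SS_STATES)}
    for k in members:
        conf = ens.conformations[k]
        for r, state in enumerate(collapse_ss(secondary_structure(conf))):
            counts[r, state_idx[state]] += 1
        rgs.append(radius_of_gyration(conf))
        e2e.append(end_to_end_distance(conf))
    return ClusterDescriptors(
        ss_propensity=counts / len(members),
        rg_mean=float(np.mean(rgs)),
        rg_sd=float(np.std(rgs)),
        end_to_end_mean=float(np.mean(e2e)),
    )


def characterize_ensemble(ens: Ensemble, features: FeatureMatrix,
                          assignment: ClusterAssignment
                          ) -> EnsembleCharacterization:
    """Full characterization: weighted maps plus per-cluster descriptors."""
    char = characterize(features, assignment)
    for m in char.maps:
        char.descriptors[m.cluster_id] = cluster_descriptors(
            ens, assignment.members(m.cluster_id)
        )
    return char


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _plot_map(values: np.ndarray, title: str, path: Path,
              cbar_label: str = "contact value") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(values, origin="lower", vmin=0, vmax=max(1.0, values.max()),
                   cmap="viridis", extent=(0.5, len(values) + 0.5,
                                           0.5, len(values) + 0.5))
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=cbar_label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(char: EnsembleCharacterization, ens: Ensemble,
           assignment: ClusterAssignment, outdir: str | Path,
           n_representatives: int = 10, seed: int = 0,
           binary_threshold: float = 8.0) -> dict:
    """Write the characterization to disk.

    Produces ``summary.json`` (weights, descriptors, file pointers),
    one map image and one multi-model PDB of randomly sampled
    representative conformations per cluster, and the naive binary
    contact-probability map of the whole ensemble for contrast.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    summary: dict = {
        "n_conformations": ens.n_conformations,
        "sequence": ens.sequence,
        "K": char.K,
        "clusters": [],
    }
    if char.noise_fraction > 0:
        summary["noise_fraction"] = char.noise_fraction

    naive = mean_binary_contact_map(ens, threshold=binary_threshold)
    _plot_map(naive, f"binary contact probability (<= {binary_threshold:g} A)",
              outdir / "naive_binary_map.png", "contact probability")
    np.savetxt(outdir / "naive_binary_map.csv", naive, delimiter=",", fmt="%.6f")

    labels_csv = outdir / "labels.csv"
    with open(labels_csv, "w") as fh:
        fh.write("conformation,label\n")
        for k, lab in enumerate(assignment.labels):
            fh.write(f"{k},{int(lab)}\n")

    for m in char.maps:
        cid = m.cluster_id
        members = assignment.members(cid)
        map_png = outdir / f"cluster_{cid:02d}_map.png"
        _plot_map(m.values, f"cluster {cid} (p = {m.weight:.3f})", map_png)
        sample = rng.choice(members, size=min(n_representatives, len(members)),
                            replace=False)
        pdb_path = outdir / f"cluster_{cid:02d}_representatives.pdb"
        write_ensemble_pdb(ens, pdb_path, indices=sorted(int(s) for s in sample))
        entry = {
            "cluster_id": cid,
            "weight": m.weight,
            "occupancy": m.occupancy,
            "map_image": map_png.name,
            "representatives": pdb_path.name,
        }
        desc = char.descriptors.get(cid)
        if desc is not None:
            entry["rg_mean"] = desc.rg_mean
            entry["rg_sd"] = desc.rg_sd
            entry["end_to_end_mean"] = desc.end_to_end_mean
            entry["ss_propensity"] = {
                state: [float(x) for x in desc.ss_propensity[:, s]]
                for s, state in enumerate(SS_STATES)
            }
        summary["clusters"].append(entry)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
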