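"""Backbone hydrogen bonds, helicity, and bound-peptide conformation classes.

The analyses here quantify the central structural observable of helical
histone-tail readout: whether the H3 N-terminal peptide forms the
intrapeptide i->i+4 (and i->i+3 / i->i+5) backbone hydrogen bonds of a
helical turn when bound to a PHD finger, and how often it does so across a
conformer ensemble.

Hydrogen bonds between backbone amides are scored with the classic
Kabsch--Sander electrostatic model: the amide hydrogen is reconstructed
geometrically (1.00 A from N, anti-parallel to the preceding carbonyl) and

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond called when E < -0.5 kcal/mol.  A residue counts as helical when
it sits inside a minimal helix of turn length n in {3, 4, 5} (alpha, 3_10 or
pi): two consecutive n-turns starting at residues i and i+1 mark residues
i+1 ... i+n helical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chain import ConformerEnsemble, PeptideChain

KS_COUPLING = 27.888  # kcal/mol * A, q1*q2*332 of Kabsch & Sander
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
NH_BOND_LENGTH = 1.00  # A
HELIX_TURNS = (3, 4, 5)  # alpha, 3_10, pi
MIN_SEQ_SEPARATION = 2  # skip donor->acceptor pairs closer in sequence

SIDECHAIN_DISTANCE_CUTOFF = 3.5  # A, heavy-atom donor-acceptor
SIDECHAIN_ANGLE_CUTOFF = 120.0  # degrees at the donor


@dataclass(frozen=True)
class HydrogenBond:
    donor_index: int
    acceptor_index: int
    donor_atom: str
    acceptor_atom: str
    energy: float  # kcal/mol for backbone-backbone, else heavy-atom distance in A
    kind: str  # "backbone-backbone" | "sidechain-backbone"


@dataclass
class HelicityProfile:
    """Per-residue helical fractions of an ensemble, summarized over replicas."""

    indices: list[int]
    pooled: np.ndarray  # frame-weighted fraction over all retained frames
    per_replica: dict[int, np.ndarray]
    median: np.ndarray  # across replicas
    iqr: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "residue": self.indices,
            "fraction": self.pooled,
            "median": self.median,
            "iqr": self.iqr,
        })


@dataclass
class ConformationClass:
    label: str  # "helical" | "bent" | "extended"
    helical_residues: int
    backbone_hbonds: int
    end_to_end_ratio: float
    evidence: dict = field(default_factory=dict)


def _amide_hydrogens(chain: PeptideChain) -> dict[int, np.ndarray]:
    """Reconstructed amide H per donor-eligible residue.

    The first residue has no preceding carbonyl and prolines have no amide
    hydrogen; both are silently ineligible as donors.
    """
    out: dict[int, np.ndarray] = {}
    for prev, res in zip(chain.residues, chain.residues[1:]):
        if res.name == "PRO":
            continue
        if not (prev.complete and res.complete):
            continue
        co = prev["C"] - prev["O"]
        co /= np.linalg.norm(co)
        out[res.index] = res["N"] + NH_BOND_LENGTH * co
    return out


def hbond_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch--Sander electrostatic energy of an N-H...O=C contact."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    return float(KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    chain: PeptideChain,
    include_sidechain: bool = False,
    energy_cutoff: float = HBOND_ENERGY_CUTOFF,
    sidechain_distance_cutoff: float = SIDECHAIN_DISTANCE_CUTOFF,
    sidechain_angle_cutoff: float = SIDECHAIN_ANGLE_CUTOFF,
) -> list[HydrogenBond]:
    """All intrapeptide hydrogen bonds of one conformation, donor perspective.

    Backbone-backbone bonds use the electrostatic criterion above; residues
    with missing backbone atoms are excluded.  With ``include_sidechain``,
    polar sidechain heavy atoms are paired against backbone N (as acceptor
    from the backbone donor) and backbone O (sidechain donor) under a
    distance cutoff, plus an angle cutoff at the donor where the donor's
    antecedent atom is available.
    """
    complete = [r for r in chain.residues if r.complete]
    if len(complete) < 2:
        raise ValueError("need at least 2 complete residues")
    hydrogens = _amide_hydrogens(chain)
    bonds: list[HydrogenBond] = []
    for donor in complete:
        h = hydrogens.get(donor.index)
        if h is None:
            continue
        for acceptor in complete:
            if abs(donor.index - acceptor.index) < MIN_SEQ_SEPARATION:
                continue
            e = hbond_energy(donor["N"], h, acceptor["C"], acceptor["O"])
            if e < energy_cutoff:
                bonds.append(HydrogenBond(
                    donor.index, acceptor.index, "N", "O", e, "backbone-backbone"))
    if include_sidechain:
        bonds.extend(_sidechain_backbone_bonds(
            chain, hydrogens, sidechain_distance_cutoff, sidechain_angle_cutoff))
    return bonds


def _sidechain_backbone_bonds(chain, hydrogens, dist_cutoff, angle_cutoff):
    bonds = []
    for res in chain.residues:
        for atom in res.sidechain_polar_atoms():
            x = res[atom]
            for other in chain.residues:
                if other.index == res.index or not other.complete:
                    continue
                # sidechain donor -> backbone carbonyl O acceptor
                if np.linalg.norm(x - other["O"]) <= dist_cutoff:
                    bonds.append(HydrogenBond(
                        res.index, other.index, atom, "O",
                        float(np.linalg.norm(x - other["O"])),
                        "sidechain-backbone"))
                # backbone N-H donor -> sidechain acceptor
                h = hydrogens.get(other.index)
                d = float(np.linalg.norm(other["N"] - x))
                if d <= dist_cutoff:
                    if h is not None:
                        ang = _angle(h, other["N"], x)  # antecedent H at donor N
                        if _angle(other["CA"], other["N"], x) < angle_cutoff:
                            continue
                    bonds.append(HydrogenBond(
                        other.index, res.index, "N", atom, d, "sidechain-backbone"))
    return bonds


def backbone_hbond_set(chain: PeptideChain, **kw) -> set[tuple[int, int]]:
    """(donor, acceptor) residue-index pairs of backbone-backbone bonds."""
    return {
        (b.donor_index, b.acceptor_index)
        for b in detect_hbonds(chain, include_sidechain=False, **kw)
    }


def assign_helicity(chain: PeptideChain) -> np.ndarray:
    """Boolean per residue: inside a minimal alpha/3_10/pi helix."""
    n_res = len(chain)
    helical = np.zeros(n_res, dtype=bool)
    if n_res < 5:  # shortest minimal helix (two 3-turns) spans 5 residues
        return helical
    bonds = backbone_hbond_set(chain)
    first = chain.residues[0].index
    acceptors_with_turn = {n: set() for n in HELIX_TURNS}
    for n in HELIX_TURNS:
        for (d, a) in bonds:
            if d - a == n:
                acceptors_with_turn[n].add(a)
    for n in HELIX_TURNS:
        turns = acceptors_with_turn[n]
        for i in turns:
            if i + 1 in turns:
                lo, hi = i + 1, i + n  # residues i+1 .. i+n
                helical[lo - first: hi - first + 1] = True
    return helical


def helicity_profile(
    ensemble: ConformerEnsemble, burn_in_fraction: float = 0.25
) -> HelicityProfile:
    """Per-residue helical fraction after discarding initial frames per replica.

    The default burn-in of 0.25 mirrors analysing the last three quarters of
    each trajectory replica.  The pooled fraction is the frame-weighted mean
    over all retained frames; median and interquartile range are taken across
    the per-replica fractions.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    per_replica: dict[int, np.ndarray] = {}
    retained_counts: dict[int, int] = {}
    for rid, frames in ensemble.replicas().items():
        start = int(np.floor(burn_in_fraction * len(frames)))
        kept = frames[start:]
        if not kept:
            raise ValueError(f"burn-in leaves no frames in replica {rid}")
        marks = np.stack([assign_helicity(f) for f in kept])
        per_replica[rid] = marks.mean(axis=0)
        retained_counts[rid] = len(kept)
    rids = sorted(per_replica)
    stack = np.stack([per_replica[r] for r in rids])
    weights = np.array([retained_counts[r] for r in rids], dtype=float)
    pooled = (stack * weights[:, None]).sum(axis=0) / weights.sum()
    q1, med, q3 = np.percentile(stack, [25, 50, 75], axis=0)
    return HelicityProfile(
        indices=ensemble.indices,
        pooled=pooled,
        per_replica=per_replica,
        median=med,
        iqr=q3 - q1,
    )


EXACT_MW_MAX = 8  # exact null enumeration up to this group size


def mann_whitney_exact_threshold() -> int:
    return EXACT_MW_MAX


def compare_helicity(a: np.ndarray, b: np.ndarray) -> np.ndarray | float:
    """Two-tailed Mann--Whitney U comparison of per-replica helical fractions.

    ``a`` and ``b`` are either 1-D (replica values for one residue; returns a
    scalar p) or 2-D with shape (n_replicas, n_residues) (returns a p per
    residue).  Small samples (both groups <= 8, no ties) use the exact null
    distribution; otherwise the normal approximation with continuity and tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1 and b.ndim == 1:
        return _mw_p(a, b)
    if a.ndim == 2 and b.ndim == 2:
        if a.shape[1] != b.shape[1]:
            raise ValueError("residue dimensions differ")
        return np.array([_mw_p(a[:, j], b[:, j]) for j in range(a.shape[1])])
    raise ValueError("inputs must both be 1-D or both be 2-D")


def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 replicas per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if min(len(x), len(y)) <= EXACT_MW_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def hbond_contact_map(
    ensemble: ConformerEnsemble, burn_in_fraction: float = 0.25
):
    """Occupancy of each backbone donor->acceptor bond over retained frames.

    Returns a DataFrame indexed by donor residue with acceptor residues as
    columns; entry (d, a) is the fraction of retained frames containing the
    backbone bond N-H(d) -> C=O(a).
    """
    import pandas as pd

    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    idx = ensemble.indices
    pos = {r: i for i, r in enumerate(idx)}
    counts = np.zeros((len(idx), len(idx)))
    total = 0
    for rid, frames in ensemble.replicas().items():
        start = int(np.floor(burn_in_fraction * len(frames)))
        kept = frames[start:]
        if not kept:
            raise ValueError(f"burn-in leaves no frames in replica {rid}")
        for f in kept:
            for (d, a) in backbone_hbond_set(f):
                counts[pos[d], pos[a]] += 1
            total += 1
    return pd.DataFrame(counts / total, index=idx, columns=idx)


def classify_conformation(
    chain: PeptideChain,
    segment: tuple[int, int],
    anchor: tuple[int, int] | None = None,
    extended_ratio_cutoff: float = 0.8,
) -> ConformationClass:
    """Classify a bound peptide segment as helical, bent or extended.

    The segment (inclusive 1-based residue range) is *helical* when at least
    three consecutive residues are helix-assigned (one complete turn),
    *extended* when it has no backbone H-bond of sequence separation >= 3 and
    its CA end-to-end distance is >= ``extended_ratio_cutoff`` of the CA
    contour length, and *bent* otherwise.
    """
    lo, hi = segment
    if hi - lo + 1 < 4:
        raise ValueError("segment must span at least 4 residues")
    indices = chain.indices
    if lo < indices[0] or hi > indices[-1]:
        raise ValueError("segment outside chain")
    if anchor is not None:
        alo, ahi = anchor
        if not (ahi < lo or alo > hi):
            raise ValueError("anchor must be disjoint from segment")

    helical_flags = assign_helicity(chain)
    first = indices[0]
    seg_flags = helical_flags[lo - first: hi - first + 1]
    run = best = 0
    for v in seg_flags:
        run = run + 1 if v else 0
        best = max(best, run)

    seg_bonds = [
        (d, a) for (d, a) in backbone_hbond_set(chain)
        if lo <= d <= hi and lo <= a <= hi and abs(d - a) >= 3
    ]
    cas = np.stack([chain.residue(i)["CA"] for i in range(lo, hi + 1)])
    contour = float(np.linalg.norm(np.diff(cas, axis=0), axis=1).sum())
    end_to_end = float(np.linalg.norm(cas[-1] - cas[0]))
    ratio = end_to_end / contour if contour > 0 else 0.0

    if best >= 3:
        label = "helical"
    elif not seg_bonds and ratio >= extended_ratio_cutoff:
        label = "extended"
    else:
        label = "bent"
    return ConformationClass(
        label=label,
        helical_residues=int(seg_flags.sum()),
        backbone_hbonds=len(seg_bonds),
        end_to_end_ratio=ratio,
        evidence={
            "segment": segment,
            "anchor": anchor,
            "max_consecutive_helical": best,
            "segment_bonds": sorted(seg_bonds),
        },
    )
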