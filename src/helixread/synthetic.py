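"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its arguments and a seed, and each
plants a known ground truth that the corresponding analysis stage must
recover exactly at zero noise:

* conformer ensembles with planted per-residue helical fractions
  (frame counts are rounded deterministically, never sampled);
* free/bound HSQC peak lists with planted shift offsets;
* single-site titrations with known (K_D, N, dH) plus Gaussian heat noise;
* alignments with planted acidic-wall / Trp / double-patch rows and a
  reference row carrying BAZ2A-style construct numbering.

These are statistical stand-ins, not physical models: no force field, no
solvent, no chemical-shift physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import itc
from .census import Msa, ReferenceAnchor
from .chain import AA1_TO_3, ConformerEnsemble, PeptideChain, build_backbone
from .csp import PeakList

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)

# filler alphabet for alignment columns that must stay non-diagnostic
_NON_DIAGNOSTIC = sorted(set("ACFGHIKLMNPQRSTVY") - set("DEW"))


@dataclass
class GeneratorConfig:
    """Shared knobs for fixture regeneration; all noise levels >= 0."""

    seed: int = 0
    coordinate_jitter_A: float = 0.0
    peak_jitter_ppm: float = 0.0
    heat_noise_ucal: float = 0.0
    n_frames: int = 100
    n_sequences: int = 10
    n_residues: int = 10

    def __post_init__(self):
        for name in ("coordinate_jitter_A", "peak_jitter_ppm", "heat_noise_ucal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_ideal_chain(sequence: str, phi: float, psi: float) -> PeptideChain:
    """Ideal-geometry backbone with uniform (phi, psi) and trans peptide bonds."""
    bad = [c for c in sequence if c not in AA1_TO_3]
    if bad:
        raise ValueError(f"unknown residue letter {bad[0]!r}")
    return build_backbone(sequence, [(phi, psi)] * len(sequence))


def _helical_frame_mask(fraction: float, n_frames: int) -> np.ndarray:
    """Deterministic, evenly interleaved frame marks.

    Frame i is helical iff floor((i+1)*f + 1/2) > floor(i*f + 1/2), which
    spreads exactly floor(f * n + 1/2) helical frames evenly through the
    trajectory — so the realized fraction equals the planted one up to
    rounding, for any contiguous analysis window.
    """
    i = np.arange(n_frames)
    return np.floor((i + 1) * fraction + 0.5) > np.floor(i * fraction + 0.5)


def make_ensemble(
    sequence: str,
    helix_fraction,
    n_frames: int,
    seed: int = 0,
    n_replicas: int = 1,
    coordinate_jitter_A: float = 0.0,
) -> ConformerEnsemble:
    """Ensemble whose frames realize planted per-residue helical fractions.

    ``helix_fraction`` is a scalar or a per-residue sequence of values in
    [0, 1].  Within each frame a residue takes either ideal-helix or
    extended (phi, psi); with a constant fraction every frame is wholly
    helical or wholly extended, so the downstream helicity assignment
    recovers the planted fraction exactly at interior residues.  Varying
    fractions are honored per residue-block, but only blocks long enough to
    host a full helical turn register as helical downstream.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    fractions = np.broadcast_to(
        np.asarray(helix_fraction, dtype=float), (len(sequence),)).copy()
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("helix fractions must lie in [0, 1]")
    masks = np.stack([_helical_frame_mask(f, n_frames) for f in fractions], axis=1)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        phi_psi = [HELIX_PHI_PSI if m else EXTENDED_PHI_PSI for m in masks[i]]
        chain = build_backbone(sequence, phi_psi)
        if coordinate_jitter_A > 0:
            for res in chain:
                for a in res.atoms:
                    res.atoms[a] = res.atoms[a] + rng.normal(
                        0.0, coordinate_jitter_A, 3)
        frames.append(chain)
    replica_ids = [min(i * n_replicas // n_frames, n_replicas - 1)
                   for i in range(n_frames)]
    return ConformerEnsemble(frames, replica_ids)


def make_peak_lists(
    n_residues: int,
    shifted: dict[int, tuple[float, float]] | None = None,
    jitter_ppm: float = 0.0,
    seed: int = 0,
    n_sidechain_pairs: int = 0,
    residues: list[int] | None = None,
) -> tuple[PeakList, PeakList]:
    """Free and bound HSQC peak lists with planted (dH, dN) offsets.

    The bound list is the free list plus the planted offsets plus seeded
    Gaussian jitter on every bound peak.  Optional Asn/Gln sidechain NH2
    pairs are appended to both lists and flagged.
    """
    shifted = shifted or {}
    if residues is None:
        residues = list(range(1, n_residues + 1))
    if len(set(residues)) != len(residues):
        raise ValueError("duplicate residue id in peak list")
    if not set(shifted) <= set(residues):
        raise ValueError("shifted residues not a subset of the residue set")
    if jitter_ppm < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    dh = rng.uniform(7.5, 9.5, len(residues))
    dn = rng.uniform(105.0, 130.0, len(residues))
    free_rows = [
        {"residue": r, "label": f"R{r}", "dH_ppm": h, "dN_ppm": n,
         "sidechain": False, "assigned": True}
        for r, h, n in zip(residues, dh, dn)
    ]
    bound_rows = []
    for row in free_rows:
        off_h, off_n = shifted.get(row["residue"], (0.0, 0.0))
        bound_rows.append({
            **row,
            "dH_ppm": row["dH_ppm"] + off_h + rng.normal(0, jitter_ppm)
            if jitter_ppm > 0 else row["dH_ppm"] + off_h,
            "dN_ppm": row["dN_ppm"] + off_n + rng.normal(0, jitter_ppm)
            if jitter_ppm > 0 else row["dN_ppm"] + off_n,
        })
    for k in range(n_sidechain_pairs):
        res = int(rng.choice(residues))
        h0 = rng.uniform(6.5, 7.5)
        n0 = rng.uniform(109.0, 113.0)
        for dhh in (-0.3, 0.3):
            pair = {"residue": res, "label": f"R{res}sc", "dH_ppm": h0 + dhh,
                    "dN_ppm": n0, "sidechain": True, "assigned": True}
            free_rows.append(pair)
            bound_rows.append(dict(pair))
    return (PeakList(pd.DataFrame(free_rows)), PeakList(pd.DataFrame(bound_rows)))


def make_titration(
    kd_uM: float,
    n_sites: float,
    dh_kcal: float,
    cell_uM: float = 100.0,
    syringe_uM: float = 1500.0,
    injection_volumes_ul=itc.DEFAULT_SCHEDULE_UL,
    cell_volume_ul: float = itc.DEFAULT_CELL_UL,
    noise_sd_ucal: float = 0.0,
    seed: int = 0,
    temperature_K: float = itc.T_DEFAULT,
) -> itc.Titration:
    """Single-site titration heats with seeded Gaussian noise."""
    if noise_sd_ucal < 0:
        raise ValueError("noise_sd must be >= 0")
    t = itc.simulate_titration(
        kd_uM, n_sites, dh_kcal, cell_uM, syringe_uM,
        injection_volumes_ul, cell_volume_ul, temperature_K)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        t.heats_ucal = t.heats_ucal + rng.normal(0, noise_sd_ucal, t.heats_ucal.shape)
        t.meta["noise_sd_ucal"] = noise_sd_ucal
    t.meta["seed"] = seed
    return t


@dataclass
class SyntheticMsa:
    """Planted alignment plus the anchors needed to analyze it."""

    msa: Msa
    wall_col: int
    trp_col: int
    wall_anchor: ReferenceAnchor
    reference_id: str
    planted_ids: list[str] = field(default_factory=list)

    def planted_msa(self) -> Msa:
        """The planted rows only, without the numbering-reference row."""
        keep = [(i, r) for i, r in zip(self.msa.ids, self.msa.rows)
                if i != self.reference_id]
        return Msa([i for i, _ in keep], [r for _, r in keep])


def make_msa(
    n_sequences: int,
    wall_set: set[int],
    trp_set: set[int],
    double_patch_set: set[int],
    length: int,
    seed: int = 0,
    wall_col: int | None = None,
    trp_col: int | None = None,
    reference_wall_number: int = 1689,
) -> SyntheticMsa:
    """Ungapped alignment with planted diagnostic columns.

    Row indices in the planted sets are 1-based.  Rows in ``wall_set`` carry
    D/E at the wall column, rows in ``trp_set`` carry W at the Trp column,
    and rows in ``double_patch_set`` (which must be wall rows) additionally
    carry an acidic residue adjacent to the wall.  All other cells draw from
    non-D/E/W residues, so the planted counts are exact by construction.  A
    reference row emulating BAZ2A numbering (wall residue = 1689, acidic
    neighbour before it) is appended for anchor resolution.
    """
    if length < 3:
        raise ValueError("alignment length must be >= 3")
    idx = set(range(1, n_sequences + 1))
    for name, s in (("wall_set", wall_set), ("trp_set", trp_set),
                    ("double_patch_set", double_patch_set)):
        if not set(s) <= idx:
            raise ValueError(f"{name} not a subset of 1..{n_sequences}")
    if not set(double_patch_set) <= set(wall_set):
        raise ValueError("double-patch rows must also be wall rows")
    if wall_col is None:
        wall_col = max(2, length // 3)
    if trp_col is None:
        trp_col = max(wall_col + 2, 2 * length // 3)
    patch_col = wall_col - 1 if wall_col > 1 else wall_col + 1
    if len({wall_col, trp_col}) < 2 or patch_col == trp_col:
        raise ValueError("overlapping column designations")
    for col in (wall_col, trp_col, patch_col):
        if not 1 <= col <= length:
            raise ValueError(f"designated column {col} outside alignment")

    rng = np.random.default_rng(seed)
    ids, rows = [], []
    for i in range(1, n_sequences + 1):
        chars = list(rng.choice(_NON_DIAGNOSTIC, length))
        if i in wall_set:
            chars[wall_col - 1] = str(rng.choice(["D", "E"]))
        if i in trp_set:
            chars[trp_col - 1] = "W"
        if i in double_patch_set:
            chars[patch_col - 1] = str(rng.choice(["D", "E"]))
        ids.append(f"seq{i:03d}")
        rows.append("".join(chars))

    ref_chars = list(rng.choice(_NON_DIAGNOSTIC, length))
    ref_chars[wall_col - 1] = "E"
    ref_chars[patch_col - 1] = "D"
    reference_id = "BAZ2A_ref"
    ids.append(reference_id)
    rows.append("".join(ref_chars))
    first_number = reference_wall_number - wall_col + 1
    anchor = ReferenceAnchor(reference_id, first_number, reference_wall_number)
    return SyntheticMsa(
        msa=Msa(ids, rows),
        wall_col=wall_col,
        trp_col=trp_col,
        wall_anchor=anchor,
        reference_id=reference_id,
        planted_ids=ids[:-1],
    )
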