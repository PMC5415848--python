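"""NMR chemical shift perturbation (CSP) analysis for HSQC titrations.

Amide peak movements between a free and a ligand-bound spectrum are
combined into the weighted shift difference

    d_weighted = |dH| + 0.14 * |dN|        [ppm]

where the 0.14 factor compresses the wider 15N shift range onto the 1H
scale.  Residues are then classed by how far their shift lies above the
mean: weak (>= mu), medium (>= mu + sigma), strong (>= mu + 2 sigma).
For slow-exchange spectra, where bound peaks cannot be assigned by
following titration trajectories, the minimal-shift approach pairs each
free peak with the nearest bound peak and yields a lower bound on the true
perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

NITROGEN_SCALE = 0.14

PEAK_COLUMNS = ["residue", "label", "dH_ppm", "dN_ppm", "sidechain", "assigned"]

CLASS_COLORS = {"none": "white", "weak": "yellow", "medium": "orange", "strong": "red"}


class PeakList:
    """Residue-indexed (dH, dN) amide peak list of one HSQC spectrum."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col, default in (("label", ""), ("sidechain", False), ("assigned", True)):
            if col not in df.columns:
                df[col] = default
        df = df[PEAK_COLUMNS]
        df["residue"] = df["residue"].astype(int)
        df[["dH_ppm", "dN_ppm"]] = df[["dH_ppm", "dN_ppm"]].astype(float)
        df["sidechain"] = df["sidechain"].astype(bool)
        df["assigned"] = df["assigned"].astype(bool)
        if not np.isfinite(df[["dH_ppm", "dN_ppm"]].to_numpy()).all():
            raise ValueError("non-finite ppm value in peak list")
        backbone = df[df["assigned"] & ~df["sidechain"]]
        dup = backbone["residue"][backbone["residue"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate assigned residue id(s): {sorted(set(dup))}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "PeakList":
        return cls(pd.DataFrame(records, columns=None))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakList":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out[["dH_ppm", "dN_ppm"]] = out[["dH_ppm", "dN_ppm"]].round(3)
        out.to_csv(path, index=False)

    def backbone(self) -> pd.DataFrame:
        return self.df[self.df["assigned"] & ~self.df["sidechain"]].set_index("residue")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CspTable:
    """Per-residue shift differences with a measurement status."""

    table: pd.DataFrame  # residue, delta_H, delta_N, d_weighted, status[, tie]

    def measured(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "measured"]


@dataclass
class CspClassification:
    mu: float
    sigma: float
    thresholds: dict[str, float]  # weak/medium/strong lower bounds
    classes: pd.DataFrame  # residue, d_weighted, csp_class
    sigma_mode: str = "sample"


def weighted_shift(delta_h, delta_n, scale: float = NITROGEN_SCALE):
    """|dH| + scale * |dN|."""
    return np.abs(delta_h) + scale * np.abs(delta_n)


def weighted_csp(free: PeakList, bound: PeakList, scale: float = NITROGEN_SCALE) -> CspTable:
    """Weighted shift difference per residue over the union of both lists.

    Sidechain-flagged peaks are excluded (status ``excluded-sidechain``);
    residues present in only one spectrum carry a missing status and are
    left out of downstream statistics.
    """
    if len(free.df) == 0 or len(bound.df) == 0:
        raise ValueError("peak lists must be non-empty")
    f = free.backbone()
    b = bound.backbone()
    rows = []
    for res in sorted(set(f.index) | set(b.index)):
        if res in f.index and res in b.index:
            dh = b.at[res, "dH_ppm"] - f.at[res, "dH_ppm"]
            dn = b.at[res, "dN_ppm"] - f.at[res, "dN_ppm"]
            rows.append((res, dh, dn, float(weighted_shift(dh, dn, scale)), "measured"))
        elif res in f.index:
            rows.append((res, np.nan, np.nan, np.nan, "missing-in-bound"))
        else:
            rows.append((res, np.nan, np.nan, np.nan, "missing-in-free"))
    for pl in (free, bound):
        for res in pl.df.loc[pl.df["sidechain"], "residue"].unique():
            rows.append((int(res), np.nan, np.nan, np.nan, "excluded-sidechain"))
    table = pd.DataFrame(
        rows, columns=["residue", "delta_H", "delta_N", "d_weighted", "status"]
    ).drop_duplicates(subset=["residue", "status"]).reset_index(drop=True)
    return CspTable(table)


def classify_csp(csp: CspTable, sigma_mode: str = "sample") -> CspClassification:
    """Class residues as none/weak/medium/strong against mu, mu+s, mu+2s.

    Thresholds are computed over measured residues only; comparisons are
    inclusive (a value exactly at a threshold takes the higher class).
    sigma is the sample (n-1) standard deviation by default.
    """
    meas = csp.measured()
    if len(meas) < 2:
        raise ValueError("need at least 2 measured residues to define sigma")
    values = meas["d_weighted"].to_numpy()
    mu = float(values.mean())
    ddof = 1 if sigma_mode == "sample" else 0
    sigma = float(values.std(ddof=ddof))
    thresholds = {"weak": mu, "medium": mu + sigma, "strong": mu + 2 * sigma}

    def klass(v: float) -> str:
        if v >= thresholds["strong"]:
            return "strong"
        if v >= thresholds["medium"]:
            return "medium"
        if v >= thresholds["weak"]:
            return "weak"
        return "none"

    classes = meas[["residue", "d_weighted"]].copy()
    classes["csp_class"] = classes["d_weighted"].map(klass)
    return CspClassification(mu, sigma, thresholds, classes.reset_index(drop=True),
                             sigma_mode=sigma_mode)


def minimal_shift(free: PeakList, bound_peaks: PeakList,
                  scale: float = NITROGEN_SCALE) -> CspTable:
    """Nearest-bound-peak shift estimate for slow-exchange spectra.

    Distance metric: sqrt(dH^2 + (scale * dN)^2).  Bound peaks need no
    assignment and may be matched by several free peaks.  Exact ties are
    broken toward the smaller dH, then smaller dN, and flagged.
    """
    cand = bound_peaks.df[~bound_peaks.df["sidechain"]]
    if len(cand) == 0:
        raise ValueError("bound peak set is empty")
    cand = cand.sort_values(["dH_ppm", "dN_ppm"]).reset_index(drop=True)
    ch = cand["dH_ppm"].to_numpy()
    cn = cand["dN_ppm"].to_numpy()
    rows = []
    for res, row in free.backbone().iterrows():
        dh = ch - row["dH_ppm"]
        dn = cn - row["dN_ppm"]
        dist = np.sqrt(dh ** 2 + (scale * dn) ** 2)
        best = np.flatnonzero(np.isclose(dist, dist.min(), rtol=0, atol=1e-12))
        j = best[0]  # candidates pre-sorted by (dH, dN): first wins ties
        rows.append((res, dh[j], dn[j],
                     float(weighted_shift(dh[j], dn[j], scale)),
                     "measured", len(best) > 1))
    table = pd.DataFrame(
        rows, columns=["residue", "delta_H", "delta_N", "d_weighted", "status", "tie"]
    )
    return CspTable(table)


def export_csp_map(classification: CspClassification, roster,
                   path: str | Path | None = None) -> pd.DataFrame:
    """Per-residue (class, color) table for driving a molecular-graphics colorer."""
    roster = set(int(r) for r in roster)
    rows = []
    for _, rec in classification.classes.iterrows():
        res = int(rec["residue"])
        if res not in roster:
            warnings.warn(f"classified residue {res} absent from structure roster")
        rows.append((res, rec["csp_class"], CLASS_COLORS[rec["csp_class"]]))
    out = pd.DataFrame(rows, columns=["residue", "csp_class", "color"])
    if path is not None:
        out.to_csv(path, index=False)
    return out
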