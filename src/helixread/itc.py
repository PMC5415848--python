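"""Single-site ITC isotherm simulation, fitting, and derived thermodynamics.

Models a standard titration-calorimetry experiment: ligand at syringe
concentration X_syr is injected stepwise into a cell of volume V0 holding
macromolecule at M0, and each injection's heat reports on the change in
bound-site occupancy.  With N identical sites of dissociation constant K_D,
the occupancy Theta after any injection solves the single-site (Wiseman)
quadratic

    Theta^2 - Theta * (1 + X/(N*M) + K_D/(N*M)) + X/(N*M) = 0

(smaller root), where M and X are the running cell concentrations after the
standard displaced-volume (perfusion) correction.  Derived quantities use

    dG = R*T*ln(K_D [M]),   T*dS = dH - dG,   R = 1.9872e-3 kcal/(mol K)

with errors propagated as d(dG) = R*T*dK_D/K_D and
d(TdS) = sqrt(d(dH)^2 + d(dG)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_KCAL = 1.9872e-3  # kcal / (mol K)
T_DEFAULT = 298.15  # K, 25 C
DEFAULT_SCHEDULE_UL = (0.4,) + (2.0,) * 19  # one small pre-injection then 19 x 2 ul
DEFAULT_CELL_UL = 200.0
KCAL_TO_UCAL = 1e9
KD_CEILING_UM = 1000.0  # weak binders reported as a bound above this


@dataclass
class Titration:
    """Injection schedule and measured (or simulated) heats of one titration."""

    temperature_K: float
    cell_volume_ul: float
    cell_uM: float
    syringe_uM: float
    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_ul.size == 0:
            raise ValueError("empty injection schedule")
        if np.any(self.injection_volumes_ul <= 0):
            raise ValueError("injection volumes must be positive")
        if self.cell_uM <= 0 or self.syringe_uM <= 0 or self.cell_volume_ul <= 0:
            raise ValueError("concentrations and cell volume must be positive")
        if self.heats_ucal.shape != self.injection_volumes_ul.shape:
            raise ValueError("heats and injection volumes must align")

    def molar_ratios(self) -> np.ndarray:
        """Ligand:macromolecule molar ratio in the cell after each injection."""
        _, m, x = _running_concentrations(
            self.cell_volume_ul, self.cell_uM, self.syringe_uM,
            self.injection_volumes_ul)
        return x / m

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temp_K={self.temperature_K}\n")
            fh.write(f"# cell_ul={self.cell_volume_ul}\n")
            fh.write(f"# cell_uM={self.cell_uM}\n")
            fh.write(f"# syringe_uM={self.syringe_uM}\n")
            pd.DataFrame({
                "volume_ul": self.injection_volumes_ul,
                "heat_ucal": self.heats_ucal,
            }).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Titration":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    header[key.strip()] = float(val)
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        return cls(
            temperature_K=header.get("temp_K", T_DEFAULT),
            cell_volume_ul=header["cell_ul"],
            cell_uM=header["cell_uM"],
            syringe_uM=header["syringe_uM"],
            injection_volumes_ul=df["volume_ul"].to_numpy(),
            heats_ucal=df["heat_ucal"].to_numpy(),
        )


@dataclass
class BindingFit:
    kd_uM: float
    kd_err_uM: float
    n: float
    n_err: float
    dh_kcal: float
    dh_err_kcal: float
    baseline_ucal: float
    c_value: float
    residual_norm: float
    converged: bool
    n_fixed: bool = False
    kd_is_bound: bool = False  # True: kd_uM is a lower bound (weak binder)
    low_c_warning: bool = False

    def kd_display(self) -> str:
        return f">{self.kd_uM:g}" if self.kd_is_bound else f"{self.kd_uM:g}"


@dataclass
class ThermoRow:
    kd_uM: float
    kd_err_uM: float
    n: float
    n_err: float
    dh_kcal: float
    dh_err_kcal: float
    tds_kcal: float
    tds_err_kcal: float
    dg_kcal: float
    dg_err_kcal: float
    temperature_K: float = T_DEFAULT

    def rounded(self) -> dict:
        """Values at customary table precision (dG two decimals, TdS one)."""
        return {
            "dG": round(self.dg_kcal, 2), "dG_err": round(self.dg_err_kcal, 2),
            "TdS": round(self.tds_kcal, 1), "TdS_err": round(self.tds_err_kcal, 1),
        }


def _running_concentrations(cell_ul, cell_uM, syringe_uM, volumes_ul):
    """Cell concentrations (M) after each injection with perfusion correction.

    The cell is overfilled and each injection displaces an equal volume; the
    standard correction treats the displaced liquid as holding the mean of
    pre- and post-injection concentrations.
    """
    dv = np.cumsum(volumes_ul) / cell_ul  # cumulative injected / cell volume
    m = cell_uM * 1e-6 * (1 - dv / 2) / (1 + dv / 2)
    x = syringe_uM * 1e-6 * dv / (1 + dv / 2)
    return dv, m, x


def wiseman_occupancy(x_total: np.ndarray, m_total: np.ndarray,
                      kd_M: float, n_sites: float) -> np.ndarray:
    """Fraction of binding sites occupied, from the single-site quadratic."""
    s = n_sites * m_total  # site concentration
    b = 1 + x_total / s + kd_M / s
    disc = b * b - 4 * x_total / s
    if np.any(disc < 0):
        raise ValueError("negative discriminant in binding quadratic")
    theta = (b - np.sqrt(disc)) / 2
    if np.any((theta < -1e-12) | (theta > 1 + 1e-12)):
        raise ValueError("occupancy outside [0, 1]: inconsistent geometry")
    return np.clip(theta, 0.0, 1.0)


def simulate_titration(
    kd_uM: float,
    n_sites: float,
    dh_kcal: float,
    cell_uM: float,
    syringe_uM: float,
    injection_volumes_ul=DEFAULT_SCHEDULE_UL,
    cell_volume_ul: float = DEFAULT_CELL_UL,
    temperature_K: float = T_DEFAULT,
) -> Titration:
    """Noiseless per-injection heats (ucal) of a single-site titration."""
    if kd_uM <= 0:
        raise ValueError("K_D must be positive")
    volumes = np.asarray(injection_volumes_ul, dtype=float)
    heats = _model_heats(
        np.log(1.0 / (kd_uM * 1e-6)), dh_kcal, n_sites, 0.0,
        cell_volume_ul, cell_uM, syringe_uM, volumes)
    return Titration(
        temperature_K=temperature_K,
        cell_volume_ul=cell_volume_ul,
        cell_uM=cell_uM,
        syringe_uM=syringe_uM,
        injection_volumes_ul=volumes,
        heats_ucal=heats,
        meta={"simulated": True, "kd_uM": kd_uM, "n": n_sites, "dh_kcal": dh_kcal},
    )


def _model_heats(ln_ka, dh_kcal, n_sites, baseline_ucal,
                 cell_ul, cell_uM, syringe_uM, volumes_ul) -> np.ndarray:
    kd_M = np.exp(-ln_ka)
    dv, m, x = _running_concentrations(cell_ul, cell_uM, syringe_uM, volumes_ul)
    theta = wiseman_occupancy(x, m, kd_M, n_sites)
    v0_l = cell_ul * 1e-6
    q = n_sites * theta * m * dh_kcal * v0_l * KCAL_TO_UCAL  # cell heat content
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (volumes_ul / cell_ul) * (q + q_prev) / 2
    return dq + baseline_ucal


def subtract_blank(sample: Titration, blank: Titration) -> Titration:
    """Subtract a ligand-into-buffer heat-of-dilution titration."""
    if sample.injection_volumes_ul.shape != blank.injection_volumes_ul.shape or \
            not np.allclose(sample.injection_volumes_ul, blank.injection_volumes_ul):
        raise ValueError("sample and blank injection schedules differ")
    out = Titration(
        temperature_K=sample.temperature_K,
        cell_volume_ul=sample.cell_volume_ul,
        cell_uM=sample.cell_uM,
        syringe_uM=sample.syringe_uM,
        injection_volumes_ul=sample.injection_volumes_ul.copy(),
        heats_ucal=sample.heats_ucal - blank.heats_ucal,
        meta=dict(sample.meta),
    )
    out.meta["blank_subtracted"] = True
    return out


def fit_single_site(
    titration: Titration,
    discard_first: bool = True,
    fix_n: float | None = None,
    kd_ceiling_uM: float = KD_CEILING_UM,
) -> BindingFit:
    """Nonlinear least-squares fit of the single-site model to heats.

    Fits (ln K_A, dH, N, baseline); N may be pinned with ``fix_n``.  The
    first injection (small pre-injection volume) is discarded by default.
    When the Wiseman c-value (N*M0/K_D) falls below 1 the isotherm carries
    little shape information and, if the fitted K_D exceeds the ceiling,
    the result is reported as a lower bound on K_D instead.
    """
    volumes = titration.injection_volumes_ul
    heats = titration.heats_ucal
    start = 1 if discard_first and len(volumes) > 1 else 0
    use = slice(start, None)
    if len(volumes[use]) < 3:
        raise ValueError("need at least 3 usable injections")
    if np.allclose(heats[use], 0.0):
        raise ValueError("all heats are zero: nothing to fit")

    m0 = titration.cell_uM * 1e-6
    sign = -1.0 if np.median(heats[use]) < 0 else 1.0
    dh0 = sign * max(np.abs(heats[use]).max(), 1.0) / (
        m0 * titration.cell_volume_ul * 1e-6 * KCAL_TO_UCAL) * 4
    n0 = fix_n if fix_n is not None else 1.0

    def residuals(p):
        if fix_n is None:
            ln_ka, dh, n, base = p
        else:
            ln_ka, dh, base = p
            n = fix_n
        model = _model_heats(ln_ka, dh, n, base,
                             titration.cell_volume_ul, titration.cell_uM,
                             titration.syringe_uM, volumes)
        return model[use] - heats[use]

    best = None
    for kd0 in (m0 / 10, m0, 10 * m0):  # c ~ 10, 1, 0.1 starts
        p0 = [np.log(1 / kd0), dh0, n0, 0.0]
        if fix_n is not None:
            p0 = [p0[0], p0[1], p0[3]]
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None or not best.success:
        raise RuntimeError("single-site fit did not converge")

    p = best.x
    dof = max(len(heats[use]) - len(p), 1)
    s2 = 2 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(len(p), np.nan)

    if fix_n is None:
        ln_ka, dh, n, base = p
        ln_ka_err, dh_err, n_err, _ = perr
    else:
        ln_ka, dh, base = p
        ln_ka_err, dh_err, _ = perr
        n, n_err = float(fix_n), 0.0
    kd_uM = np.exp(-ln_ka) * 1e6
    kd_err_uM = kd_uM * ln_ka_err
    c = n * titration.cell_uM / kd_uM
    low_c = c < 1
    kd_is_bound = bool(low_c and kd_uM >= kd_ceiling_uM)
    if kd_is_bound:
        kd_uM, kd_err_uM = kd_ceiling_uM, float("nan")
    return BindingFit(
        kd_uM=float(kd_uM), kd_err_uM=float(kd_err_uM),
        n=float(n), n_err=float(n_err),
        dh_kcal=float(dh), dh_err_kcal=float(dh_err),
        baseline_ucal=float(base),
        c_value=float(c),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
        n_fixed=fix_n is not None,
        kd_is_bound=kd_is_bound,
        low_c_warning=bool(low_c),
    )


def derive_thermo(
    kd_uM: float, kd_err_uM: float,
    dh_kcal: float, dh_err_kcal: float,
    temperature_K: float = T_DEFAULT,
    n: float = float("nan"), n_err: float = float("nan"),
) -> ThermoRow:
    """dG, TdS and their propagated errors from (K_D +- err, dH +- err)."""
    if kd_uM <= 0:
        raise ValueError("K_D must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    rt = R_KCAL * temperature_K
    dg = rt * np.log(kd_uM * 1e-6)
    dg_err = rt * kd_err_uM / kd_uM
    tds = dh_kcal - dg
    tds_err = float(np.hypot(dh_err_kcal, dg_err))
    return ThermoRow(kd_uM, kd_err_uM, n, n_err, dh_kcal, dh_err_kcal,
                     tds, tds_err, float(dg), float(dg_err), temperature_K)


@dataclass
class FoldChange:
    ratio: float
    one_decimal: float
    nearest_int: int


def fold_change(kd_reference_uM: float, kd_other_uM: float) -> FoldChange:
    """Affinity ratio K_D(other)/K_D(reference) with rounded renderings."""
    if kd_reference_uM <= 0 or kd_other_uM <= 0:
        raise ValueError("dissociation constants must be positive")
    r = kd_other_uM / kd_reference_uM
    return FoldChange(r, round(r, 1), int(round(r)))


# --- packaged thermodynamic-parameter tables ------------------------------

TABLE_FILES = {
    "wt_peptides": "itc_thermo_wt_peptides.csv",
    "wall_mutants": "itc_thermo_acidic_wall_mutants.csv",
}


def load_thermo_table(which: str | Path) -> pd.DataFrame:
    """Load a packaged parameter table (``wt_peptides``/``wall_mutants``) or a CSV path."""
    if str(which) in TABLE_FILES:
        ref = resources.files("helixread.data") / TABLE_FILES[str(which)]
        with resources.as_file(ref) as p:
            return pd.read_csv(p, dtype=str)
    return pd.read_csv(which, dtype=str)


def _parse_value(text) -> float | None:
    """Parse a table cell; None for N.D./bounds/empty.  Handles Unicode minus."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip().replace("−", "-").replace("–", "-")
    if s in ("", "N.D.", "ND", "n.d.", "no binding", "No binding") or s.startswith(">"):
        return None
    return float(s)


@dataclass
class TableValidation:
    report: pd.DataFrame
    n_checked: int
    n_skipped: int
    max_dg_dev: float
    max_tds_dev: float

    @property
    def all_consistent(self) -> bool:
        return bool(self.report.loc[self.report["checked"], "ok"].all())


def validate_table(
    table: pd.DataFrame | str | Path,
    temperature_K: float = T_DEFAULT,
    dg_tol: float = 0.03,
    tds_tol: float = 0.1,
) -> TableValidation:
    """Recompute dG and TdS for each numeric row and compare to printed values.

    Rows whose K_D is a bound (">1000") or not determined are skipped with a
    note.  Tolerances default to the rounding granularity of typical printed
    tables.
    """
    if not isinstance(table, pd.DataFrame):
        table = load_thermo_table(table)
    rows = []
    for i, rec in table.iterrows():
        kd = _parse_value(rec.get("kd_uM"))
        dh = _parse_value(rec.get("dh_kcal"))
        dg_printed = _parse_value(rec.get("dg_kcal"))
        tds_printed = _parse_value(rec.get("tds_kcal"))
        label = " / ".join(str(rec[c]) for c in ("peptide", "protein") if c in rec and
                           isinstance(rec[c], str))
        if kd is None or dh is None or dg_printed is None or tds_printed is None:
            rows.append({"row": label, "checked": False, "ok": None,
                         "note": "skipped: K_D bound or N.D."})
            continue
        if kd <= 0:
            raise ValueError(f"malformed row {label!r}: nonpositive K_D")
        tr = derive_thermo(kd, _parse_value(rec.get("kd_err_uM")) or 0.0,
                           dh, _parse_value(rec.get("dh_err_kcal")) or 0.0,
                           temperature_K)
        dg_dev = abs(tr.dg_kcal - dg_printed)
        tds_dev = abs(tr.tds_kcal - tds_printed)
        rows.append({
            "row": label, "checked": True,
            "dg_recomputed": tr.dg_kcal, "dg_printed": dg_printed, "dg_dev": dg_dev,
            "tds_recomputed": tr.tds_kcal, "tds_printed": tds_printed,
            "tds_dev": tds_dev,
            "ok": bool(dg_dev <= dg_tol and tds_dev <= tds_tol),
            "note": "",
        })
    report = pd.DataFrame(rows)
    checked = report[report["checked"] == True]  # noqa: E712
    return TableValidation(
        report=report,
        n_checked=int(len(checked)),
        n_skipped=int(len(report) - len(checked)),
        max_dg_dev=float(checked["dg_dev"].max()) if len(checked) else float("nan"),
        max_tds_dev=float(checked["tds_dev"].max()) if len(checked) else float("nan"),
    )
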