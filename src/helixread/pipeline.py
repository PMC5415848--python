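"""Reproducible multi-stage runs: config validation, manifests, fixtures.

A run is described by a flat YAML config (global keys plus a ``stages``
list); each stage maps onto one analysis entry point, outputs land in the
run directory, and a manifest records inputs (with content hashes),
parameters, outputs and the package version so a run can be audited and
repeated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, census, csp, itc, pdbio, propensity, structure, synthetic

log = logging.getLogger("helixread")


@dataclass
class RunConfig:
    stages: list[dict]
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        stages = doc.get("stages", [])
        if not stages:
            raise ValueError("config lists no stages")
        return cls(
            stages=stages,
            out_dir=Path(doc.get("out", "helixread_run")),
            seed=int(doc.get("seed", 0)),
            log_level=doc.get("log_level", "INFO"),
            params=doc.get("params", {}),
        )

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("empty stage list")
        for st in self.stages:
            if "stage" not in st:
                raise ValueError(f"stage entry without a 'stage' key: {st}")
            for key in ("pdb", "msa", "free", "bound", "in", "table"):
                val = st.get(key)
                if val is not None and str(val) not in itc.TABLE_FILES and \
                        not Path(val).exists():
                    raise FileNotFoundError(f"stage input {key}={val} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute each requested stage; return (and write) the run manifest."""
    config.validate()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = {"version": __version__, "seed": config.seed, "stages": []}
    for st in config.stages:
        name = st["stage"]
        entry = {"stage": name, "params": {k: v for k, v in st.items() if k != "stage"},
                 "inputs": {}, "outputs": []}
        for key in ("pdb", "msa", "free", "bound", "in", "table"):
            val = st.get(key)
            if val is not None and Path(str(val)).exists():
                entry["inputs"][key] = _sha256(Path(val))
        try:
            entry["outputs"] = _run_stage(name, st, config)
            entry["status"] = "ok"
        except Exception as exc:
            entry["status"] = f"failed: {exc}"
            manifest["stages"].append(entry)
            _write_manifest(manifest, config.out_dir)
            raise
        manifest["stages"].append(entry)
    _write_manifest(manifest, config.out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _parse_range(text: str) -> tuple[int, int]:
    lo, _, hi = str(text).partition(":")
    return int(lo), int(hi)


def _run_stage(name: str, st: dict, config: RunConfig) -> list[str]:
    out = config.out_dir
    if name == "helicity":
        ens = pdbio.read_structures(st["pdb"], chain_id=st.get("chain"))
        n_rep = int(st.get("replicas", 1))
        if n_rep > 1:
            ens.replica_ids = [min(i * n_rep // len(ens), n_rep - 1)
                               for i in range(len(ens))]
        prof = structure.helicity_profile(ens, float(st.get("burn_in", 0.25)))
        path = out / "helicity_profile.csv"
        prof.as_frame().to_csv(path, index=False)
        return [str(path)]
    if name == "classify":
        ens = pdbio.read_structures(st["pdb"], chain_id=st.get("chain"))
        cc = structure.classify_conformation(
            ens.frames[0], _parse_range(st["segment"]),
            _parse_range(st["anchor"]) if st.get("anchor") else None)
        path = out / "conformation.json"
        path.write_text(json.dumps({
            "class": cc.label, "helical_residues": cc.helical_residues,
            "backbone_hbonds": cc.backbone_hbonds,
            "end_to_end_ratio": cc.end_to_end_ratio,
            "evidence": {k: str(v) for k, v in cc.evidence.items()},
        }, indent=2))
        return [str(path)]
    if name == "census":
        msa = census.read_alignment(st["msa"], st.get("format"))
        wall_id, _, wall_num = st["wall_ref"].partition(":")
        anchor = census.ReferenceAnchor(
            wall_id, int(st.get("wall_ref_start", 1)), int(wall_num))
        wall_col = census.map_reference_position(msa, anchor)
        trp_id, _, trp_num = st["trp_ref"].partition(":")
        trp_anchor = census.ReferenceAnchor(
            trp_id, int(st.get("trp_ref_start", 1)), int(trp_num))
        trp_col = census.map_reference_position(msa, trp_anchor)
        cls = census.classify_rows(msa, wall_col, trp_col)
        summary = census.census_summary(cls)
        flags = out / "census_flags.csv"
        census.classifications_frame(cls).to_csv(flags, index=False)
        spath = out / "census_summary.json"
        spath.write_text(json.dumps({
            "n_total": summary.n_total, "n_acidic_wall": summary.n_acidic_wall,
            "n_trp": summary.n_trp, "n_both": summary.n_both,
            "n_double_patch": summary.n_double_patch,
            "wall_col": wall_col, "trp_col": trp_col,
        }, indent=2))
        return [str(flags), str(spath)]
    if name == "csp":
        free = csp.PeakList.from_csv(st["free"])
        bound = csp.PeakList.from_csv(st["bound"])
        if st.get("minimal_shift"):
            table = csp.minimal_shift(free, bound)
        else:
            table = csp.weighted_csp(free, bound)
        cls = csp.classify_csp(table)
        tpath = out / "csp_table.csv"
        table.table.to_csv(tpath, index=False)
        cpath = out / "csp_classes.csv"
        cls.classes.to_csv(cpath, index=False)
        return [str(tpath), str(cpath)]
    if name == "itc_fit":
        t = itc.Titration.from_csv(st["in"])
        fix_n = st.get("fix_n")
        fit = itc.fit_single_site(t, fix_n=float(fix_n) if fix_n else None)
        row = itc.derive_thermo(fit.kd_uM, fit.kd_err_uM, fit.dh_kcal,
                                fit.dh_err_kcal, t.temperature_K, fit.n, fit.n_err)
        path = out / "itc_fit.json"
        path.write_text(json.dumps({
            "kd_uM": fit.kd_uM, "kd_err_uM": fit.kd_err_uM,
            "kd_display": fit.kd_display(),
            "n": fit.n, "n_err": fit.n_err,
            "dh_kcal": fit.dh_kcal, "dh_err_kcal": fit.dh_err_kcal,
            "dg_kcal": row.dg_kcal, "dg_err_kcal": row.dg_err_kcal,
            "tds_kcal": row.tds_kcal, "tds_err_kcal": row.tds_err_kcal,
            "c_value": fit.c_value, "low_c_warning": fit.low_c_warning,
        }, indent=2))
        return [str(path)]
    if name == "itc_validate":
        v = itc.validate_table(st.get("table", "wt_peptides"))
        path = out / "table_validation.csv"
        v.report.to_csv(path, index=False)
        return [str(path)]
    if name == "propensity":
        seqs = st["sequences"]
        window = _parse_range(st.get("window", "3:8"))
        ranked = propensity.rank_variants(list(seqs), window)
        path = out / "propensity_ranking.csv"
        import pandas as pd

        pd.DataFrame([
            {"rank": r.rank, "sequence": r.sequence, "score_kcal": r.score,
             "tied": r.tied} for r in ranked
        ]).to_csv(path, index=False)
        return [str(path)]
    raise ValueError(f"unknown stage {name!r}")


def make_fixtures(out_dir: str | Path, seed: int = 0,
                  config: synthetic.GeneratorConfig | None = None) -> list[Path]:
    """Regenerate every synthetic input plus the packaged parameter tables."""
    cfg = config or synthetic.GeneratorConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ens = synthetic.make_ensemble("ARTKQTARKS", 0.4, cfg.n_frames,
                                  seed=cfg.seed, n_replicas=4,
                                  coordinate_jitter_A=cfg.coordinate_jitter_A)
    p = out / "h3_ensemble_planted40.pdb"
    pdbio.write_ensemble(ens, p)
    written.append(p)

    free, bound = synthetic.make_peak_lists(
        20, {5: (0.10, 0.50), 6: (0.05, 0.20), 12: (0.30, 1.00)},
        jitter_ppm=cfg.peak_jitter_ppm, seed=cfg.seed, n_sidechain_pairs=2)
    for name, pl in (("hsqc_free.csv", free), ("hsqc_bound.csv", bound)):
        path = out / name
        pl.to_csv(path)
        written.append(path)

    t = synthetic.make_titration(51, 1.35, -5.8,
                                 noise_sd_ucal=cfg.heat_noise_ucal, seed=cfg.seed)
    p = out / "titration_h3_10mer.csv"
    t.to_csv(p)
    written.append(p)

    sm = synthetic.make_msa(cfg.n_sequences, {1, 2, 3, 4}, {5, 6, 7}, {1},
                            60, seed=cfg.seed)
    p = out / "phd_alignment.fasta"
    with open(p, "w") as fh:
        for rid, row in zip(sm.msa.ids, sm.msa.rows):
            fh.write(f">{rid}\n{row}\n")
    written.append(p)

    for which in itc.TABLE_FILES:
        df = itc.load_thermo_table(which)
        p = out / itc.TABLE_FILES[which]
        df.to_csv(p, index=False)
        written.append(p)
    return written
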