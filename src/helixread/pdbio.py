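"""Multi-model PDB input/output for peptide conformer ensembles.

Reading goes through gemmi; each MODEL record becomes one ensemble frame
(a file without MODEL records is a single frame).  Alternate locations are
resolved to the highest-occupancy conformer and insertion codes are
rejected.  Writing emits plain fixed-format PDB, one MODEL per frame.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np

from .chain import BACKBONE_ATOMS, ConformerEnsemble, PeptideChain, Residue


def read_structures(
    path: str | Path,
    chain_id: str | None = None,
    replica_ids: list[int] | None = None,
) -> ConformerEnsemble:
    """Read a (multi-model) PDB file into a ConformerEnsemble.

    ``replica_ids`` optionally tags each model with a replica; default is a
    single replica.  Residues missing any backbone atom are flagged with a
    warning and kept (H-bond search skips them).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    frames = []
    for model in st:
        chains = list(model)
        if chain_id is not None:
            chains = [c for c in chains if c.name == chain_id]
            if not chains:
                raise ValueError(f"chain {chain_id!r} not found in model {model.name}")
        chain = chains[0]
        frames.append(_convert_chain(chain, path))
    roster = frames[0].roster()
    for k, f in enumerate(frames[1:], start=2):
        if f.roster() != roster:
            raise ValueError(f"model {k} residue roster differs from model 1")
    return ConformerEnsemble(frames, replica_ids)


def _convert_chain(chain: gemmi.Chain, path) -> PeptideChain:
    residues = []
    for res in chain:
        if res.seqid.icode not in ("", " "):
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at residue "
                f"{res.seqid.num} in {path}: not supported"
            )
        atoms: dict[str, np.ndarray] = {}
        occ: dict[str, float] = {}
        for atom in res:
            if atom.name in atoms and atom.occ <= occ[atom.name]:
                continue  # keep highest-occupancy altloc
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            occ[atom.name] = atom.occ
        residues.append(Residue(res.seqid.num, res.name.upper(), atoms))
    # renumber to 1-based contiguity, preserving order
    for i, r in enumerate(residues):
        r.index = i + 1
    incomplete = [r.index for r in residues if not r.complete]
    if incomplete:
        warnings.warn(
            f"residues {incomplete} lack backbone atoms and are "
            "excluded from hydrogen-bond analysis"
        )
    return PeptideChain(residues)


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write one MODEL per frame in fixed-format PDB."""
    lines = []
    multi = len(ensemble) > 1
    for m, frame in enumerate(ensemble, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for res in frame:
            for name in (*BACKBONE_ATOMS, *sorted(set(res.atoms) - set(BACKBONE_ATOMS))):
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                el = name[0]
                name_fmt = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {name_fmt} {res.name:>3s} A{res.index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
                )
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
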