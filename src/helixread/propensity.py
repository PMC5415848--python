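"""Scale-based helix-propensity scoring of peptide variants.

Ranks peptide variants by the summed per-residue free-energy cost of helix
formation over a window (lower = more helix-favoring), using a swappable
propensity scale with alanine as the zero reference.  This is an ordinal
tool: it reproduces design logic such as "K4A/Q5A stabilizes the H3 tail
helix, K4G/Q5G destabilizes it" without attempting quantitative
helix-content prediction (no nucleation/propagation model).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PropensityScale:
    name: str
    values: dict[str, float]  # residue -> ddG helix cost, kcal/mol, Ala = 0

    def __post_init__(self):
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")
        if self.values["A"] != 0.0:
            raise ValueError("alanine must be the 0.0 reference")
        if self.values["G"] <= 0.0:
            raise ValueError("glycine must have positive helix cost")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in scale {self.name!r}") from None


def load_scale(path: str | Path | None = None) -> PropensityScale:
    """Load a scale from YAML; default is the packaged consensus scale."""
    if path is None:
        ref = resources.files("helixread.data") / "helix_propensity_scale.yaml"
        with resources.as_file(ref) as p:
            doc = yaml.safe_load(Path(p).read_text())
    else:
        doc = yaml.safe_load(Path(path).read_text())
    return PropensityScale(doc.get("name", "custom"),
                           {k: float(v) for k, v in doc["values"].items()})


# observed helical span of PHD-bound H3 10-mer (helix from after T3 through R8)
DEFAULT_WINDOW = (3, 8)


def score_peptide(sequence: str, window: tuple[int, int] = DEFAULT_WINDOW,
                  scale: PropensityScale | None = None) -> float:
    """Summed helix cost (kcal/mol) over a 1-based inclusive residue window."""
    if scale is None:
        scale = load_scale()
    lo, hi = window
    if not (1 <= lo <= hi <= len(sequence)):
        raise ValueError(f"window {window} outside sequence of length {len(sequence)}")
    total = 0.0
    for ch in sequence[lo - 1:hi]:
        if ch not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {ch!r} in scoring window")
        total += scale[ch]
    return total


@dataclass
class RankedVariant:
    sequence: str
    score: float
    rank: int
    tied: bool


def rank_variants(sequences: list[str], window: tuple[int, int] = DEFAULT_WINDOW,
                  scale: PropensityScale | None = None) -> list[RankedVariant]:
    """Variants in ascending helix cost (most helix-favoring first); ties flagged."""
    if not sequences:
        raise ValueError("no sequences to rank")
    if scale is None:
        scale = load_scale()
    scored = [(s, score_peptide(s, window, scale)) for s in sequences]
    scored.sort(key=lambda t: t[1])
    out = []
    for i, (seq, sc) in enumerate(scored):
        tied = any(abs(sc - other) < 1e-12 for j, (_, other) in enumerate(scored)
                   if j != i)
        out.append(RankedVariant(seq, sc, i + 1, tied))
    return out
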