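"""Gene-list signatures.

Holds the built-in proneural (16 genes) and mesenchymal (18 genes)
glioblastoma subtype marker lists and a reader for plain-text signature
files (one gene symbol per line, ``#`` starts a comment).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .containers import ValidationError


@dataclass(frozen=True)
class SignatureSet:
    """A named, ordered, non-empty gene list."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature '{self.name}' contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, index) -> list:
        """Genes of the signature found in ``index`` (order preserved)."""
        member = set(index)
        return [g for g in self.genes if g in member]


#: Proneural glioblastoma subtype markers.
PRONEURAL = SignatureSet(
    "proneural",
    (
        "ASCL1", "DLL3", "EPHB1", "FXYD6", "GABRA3", "GRIA2", "KIF21B",
        "KLRC3", "MAPT", "OLIG2", "P2RX7", "SCG3", "SEZ6L", "SLC1A1",
        "SORCS3", "TTYH1",
    ),
)

#: Mesenchymal glioblastoma subtype markers.
MESENCHYMAL = SignatureSet(
    "mesenchymal",
    (
        "EFEMP2", "EHD2", "EMP3", "FCGR2A", "FES", "HK3", "ITGA5", "MVP",
        "NRP1", "PLAU", "PLAUR", "RRAS", "S100A11", "SERPINA1", "SERPINE1",
        "SLC16A3", "THBD", "TIMP1",
    ),
)

BUILTIN_SIGNATURES = {s.name: s for s in (PRONEURAL, MESENCHYMAL)}


def load_signature(path, name: str | None = None) -> SignatureSet:
    """Read a signature file: one gene symbol per line, ``#`` comments."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return SignatureSet(name or path.stem, tuple(genes))


def example_signature(which: str) -> SignatureSet:
    """Load one of the packaged illustrative DEG lists.

    ``which`` is ``"aspirate_down"`` or ``"aspirate_up"``.  These are
    demonstration gene lists for CLI walk-throughs, not ground truth.
    """
    fname = f"example_{which}_degs.txt"
    ref = resources.files("cusaseq.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return load_signature(p, name=which)
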