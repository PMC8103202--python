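"""Germline gene-segment reference for immunoglobulin V(D)J annotation.

A :class:`GermlineReference` holds the V, D and J gene segments of the
heavy and kappa loci together with the anchor coordinates needed for CDR3
extraction: the conserved second cysteine codon at the 3' end of every V
segment and the conserved tryptophan (heavy) / phenylalanine (kappa) codon
of every J segment.  V segments additionally carry framework/CDR boundary
coordinates used to tally somatic mutations by region.

All coordinates are 0-based half-open nucleotide positions on the germline
segment; human-readable reports convert to 1-based.

The bundled default reference is a small synthetic gene set (one murine-like
framework per locus, diversified per gene) sized for desk-scale analysis;
it is not an IMGT download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

HEAVY = "heavy"
KAPPA = "kappa"

_V_ANCHOR_AA = {"C"}
_J_ANCHOR_AA = {HEAVY: {"W"}, KAPPA: {"F", "W"}}


class GermlineError(ValueError):
    """Raised when a germline reference violates its structural invariants."""


@dataclass(frozen=True)
class Segment:
    """One germline gene segment.

    Parameters
    ----------
    name:
        Gene name without allele suffix, e.g. ``"1-22"``.
    seq:
        Nucleotide sequence, uppercase ACGT.
    anchor_start:
        Start of the anchor codon (V: 2nd-Cys; J: conserved Trp/Phe),
        0-based; ``None`` for D segments.
    regions:
        For V segments, ``{"fr1_end", "cdr1_end", "fr2_end", "cdr2_end",
        "fr3_end"}`` nucleotide boundaries (0-based half-open, FR1 starts
        at 0, ``fr3_end`` includes the 2nd-Cys codon).
    """

    name: str
    seq: str
    anchor_start: int | None = None
    regions: dict[str, int] | None = None

    def translate(self) -> str:
        n = len(self.seq) - len(self.seq) % 3
        return str(Seq(self.seq[:n]).translate())

    def anchor_codon(self) -> str | None:
        if self.anchor_start is None:
            return None
        return self.seq[self.anchor_start : self.anchor_start + 3]


@dataclass
class GermlineReference:
    """Gene segments grouped by (locus, role)."""

    pools: dict[tuple[str, str], list[Segment]] = field(default_factory=dict)

    def add(self, locus: str, role: str, segment: Segment) -> None:
        self.pools.setdefault((locus, role), []).append(segment)

    def segments(self, locus: str, role: str) -> list[Segment]:
        return self.pools.get((locus, role), [])

    def get(self, locus: str, role: str, name: str) -> Segment:
        for seg in self.segments(locus, role):
            if seg.name == name:
                return seg
        raise KeyError(f"no {locus} {role} segment named {name!r}")

    def validate(self) -> None:
        """Check anchor identities and name uniqueness; raise GermlineError."""
        for (locus, role), segs in self.pools.items():
            names = [s.name for s in segs]
            if len(set(names)) != len(names):
                raise GermlineError(f"duplicate gene names in {locus} {role}")
            for seg in segs:
                if role == "V":
                    aa = str(Seq(seg.anchor_codon()).translate())
                    if aa not in _V_ANCHOR_AA:
                        raise GermlineError(
                            f"{locus} V {seg.name}: anchor codon translates to "
                            f"{aa!r}, expected C"
                        )
                elif role == "J":
                    aa = str(Seq(seg.anchor_codon()).translate())
                    if aa not in _J_ANCHOR_AA[locus]:
                        raise GermlineError(
                            f"{locus} J {seg.name}: anchor codon translates to "
                            f"{aa!r}, expected {_J_ANCHOR_AA[locus]}"
                        )

    @classmethod
    def from_files(cls, fasta_paths: dict[tuple[str, str], Path], anchors_tsv: Path) -> "GermlineReference":
        """Build a reference from per-(locus, role) FASTA files and a sidecar TSV.

        The sidecar has columns locus, role, gene, anchor_start and, for V
        rows, the five region boundaries.
        """
        side = pd.read_csv(anchors_tsv, sep="\t", dtype={"gene": str})
        side = side.set_index(["locus", "role", "gene"])
        ref = cls()
        for (locus, role), path in fasta_paths.items():
            for rec in SeqIO.parse(str(path), "fasta"):
                name = rec.id
                anchor = None
                regions = None
                key = (locus, role, name)
                if key in side.index:
                    row = side.loc[key]
                    if pd.notna(row["anchor_start"]):
                        anchor = int(row["anchor_start"])
                    if role == "V":
                        regions = {
                            k: int(row[k])
                            for k in ("fr1_end", "cdr1_end", "fr2_end", "cdr2_end", "fr3_end")
                        }
                ref.add(locus, role, Segment(name, str(rec.seq).upper(), anchor, regions))
        ref.validate()
        return ref


def load_default_germline() -> GermlineReference:
    """Load the synthetic germline reference bundled with the package."""
    root = resources.files("polyrep").joinpath("data/germline")
    with resources.as_file(root) as d:
        return GermlineReference.from_files(
            {
                (HEAVY, "V"): d / "heavy_v.synthetic.fasta",
                (HEAVY, "D"): d / "heavy_d.synthetic.fasta",
                (HEAVY, "J"): d / "heavy_j.synthetic.fasta",
                (KAPPA, "V"): d / "kappa_v.synthetic.fasta",
                (KAPPA, "J"): d / "kappa_j.synthetic.fasta",
            },
            d / "anchors.tsv",
        )
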