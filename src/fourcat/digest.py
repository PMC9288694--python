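"""In-silico restriction digestion and fragment maps.

4C-seq resolves chromatin contacts at the level of restriction fragments:
the genome is cut at every occurrence of the enzyme's recognition site
(DpnII for the primary digest, Csp6I for the secondary), and each sequencing
read is assigned to one fragment.  This module builds the fragment map of a
genome and resolves a "viewpoint" — the genomic position whose contacts the
assay captures, typically a gene promoter — to its containing fragment.

Conventions (used by every downstream module):

* coordinates are 0-based, half-open (BED);
* cuts are placed at the first base of each recognition-site occurrence
  (a blunt-cut abstraction — real enzymes leave short overhangs, which is
  irrelevant at the 2 kb window resolution of the analysis);
* IUPAC degeneracy in the recognition site is honoured (N matches any base).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

import numpy as np
from Bio import SeqIO

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

#: Recognition sites of the enzymes used in the two-step 4C digestion design.
ENZYME_CATALOGUE = {
    "DpnII": "GATC",
    "Csp6I": "GTAC",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme, identified by name and IUPAC recognition site."""

    name: str
    recognition_site: str

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site:
            raise ValueError("recognition site must be non-empty")
        bad = set(site) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"recognition site has non-IUPAC characters: {sorted(bad)}")
        object.__setattr__(self, "recognition_site", site)

    @classmethod
    def from_name(cls, name: str) -> "RestrictionEnzyme":
        """Look up a catalogued enzyme (DpnII → GATC, Csp6I → GTAC)."""
        try:
            return cls(name, ENZYME_CATALOGUE[name])
        except KeyError:
            raise KeyError(
                f"unknown enzyme {name!r}; catalogued: {sorted(ENZYME_CATALOGUE)}"
            ) from None

    def site_pattern(self) -> re.Pattern:
        """Overlap-tolerant regex matching the recognition site."""
        body = "".join(f"[{IUPAC_DNA[c]}]" for c in self.recognition_site)
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment, 0-based half-open, with its ordinal index."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment bounds [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Viewpoint:
    """A viewpoint position resolved to its containing restriction fragment."""

    name: str
    chrom: str
    position: int
    fragment_index: int


def _find_cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> List[int]:
    seq = sequence.upper()
    site = enzyme.recognition_site
    if set(site) <= {"A", "C", "G", "T"}:
        # fast path: plain string scan (overlap-tolerant)
        cuts, pos = [], seq.find(site)
        while pos != -1:
            cuts.append(pos)
            pos = seq.find(site, pos + 1)
        return cuts
    return [m.start() for m in enzyme.site_pattern().finditer(seq)]


def digest(sequence: str, enzyme: RestrictionEnzyme, chrom: str = "chr") -> List[Fragment]:
    """Digest a sequence, returning fragments that tile [0, len(sequence)).

    A cut is placed at the start coordinate of every recognition-site
    occurrence; a sequence with no occurrence yields a single fragment.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = _find_cut_positions(sequence, enzyme)
    bounds = [0] + [c for c in cuts if c > 0] + [len(sequence)]
    bounds = sorted(set(bounds))
    return [
        Fragment(chrom, s, e, i)
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome of a genome.

    Internally stores per-chromosome boundary arrays (fragment starts plus the
    chromosome end) for vectorised lookups; `fragments()` materialises
    :class:`Fragment` objects on demand.
    """

    chrom_sizes: Dict[str, int]
    enzyme: RestrictionEnzyme
    _boundaries: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def boundaries(self, chrom: str) -> np.ndarray:
        """Fragment boundaries on `chrom`: starts plus the final end."""
        return self._boundaries[chrom]

    def n_fragments(self, chrom: str) -> int:
        return len(self._boundaries[chrom]) - 1

    def fragments(self, chrom: str) -> List[Fragment]:
        b = self._boundaries[chrom]
        return [
            Fragment(chrom, int(s), int(e), i)
            for i, (s, e) in enumerate(zip(b[:-1], b[1:]))
        ]

    def iter_fragments(self) -> Iterator[Fragment]:
        for chrom in self.chrom_sizes:
            yield from self.fragments(chrom)

    def fragment_bounds(self, chrom: str, index: int) -> Tuple[int, int]:
        b = self._boundaries[chrom]
        if not 0 <= index < len(b) - 1:
            raise IndexError(f"fragment index {index} out of range on {chrom}")
        return int(b[index]), int(b[index + 1])

    def midpoints(self, chrom: str) -> np.ndarray:
        b = self._boundaries[chrom]
        return (b[:-1] + b[1:]) // 2

    def fragment_index_at(self, chrom: str, position: int) -> int:
        """Index of the fragment containing `position` (half-open containment)."""
        if chrom not in self._boundaries:
            raise KeyError(f"chromosome {chrom!r} not in fragment map")
        size = self.chrom_sizes[chrom]
        if not 0 <= position < size:
            raise ValueError(f"position {position} out of bounds for {chrom} (len {size})")
        b = self._boundaries[chrom]
        return int(np.searchsorted(b, position, side="right") - 1)

    def to_bed(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        import pandas as pd

        rows = [
            (f.chrom, f.start, f.end, f.index)
            for f in self.iter_fragments()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def write_bed(self, path) -> None:
        self.to_bed().to_csv(path, sep="\t", header=False, index=False)


def build_fragment_map(
    genome: Mapping[str, str] | str, enzyme: RestrictionEnzyme
) -> FragmentMap:
    """Digest every chromosome of a genome into a :class:`FragmentMap`.

    `genome` is either a mapping chrom → sequence or a path to a FASTA file.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "read"):
        seqs: Dict[str, str] = {}
        for rec in SeqIO.parse(genome, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in FASTA")
            seqs[rec.id] = str(rec.seq)
        genome = seqs
    else:
        names = list(genome)
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
    if not genome:
        raise ValueError("genome has no chromosomes")
    fmap = FragmentMap(chrom_sizes={}, enzyme=enzyme)
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"chromosome {chrom!r} is empty")
        cuts = [c for c in _find_cut_positions(seq, enzyme) if c > 0]
        bounds = np.array(sorted({0, *cuts, len(seq)}), dtype=np.int64)
        fmap.chrom_sizes[chrom] = len(seq)
        fmap._boundaries[chrom] = bounds
    return fmap


def resolve_viewpoint(
    fmap: FragmentMap, chrom: str, position: int, name: str = "viewpoint"
) -> Viewpoint:
    """Resolve a (chrom, position) pair to the fragment containing it."""
    idx = fmap.fragment_index_at(chrom, position)
    return Viewpoint(name=name, chrom=chrom, position=int(position), fragment_index=idx)
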