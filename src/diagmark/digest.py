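"""In-silico double-digest restriction fragmentation.

Models the reduced-representation step of a ddRAD-seq library: two restriction
enzymes cut a reference sequence wherever their recognition sites occur, the
resulting fragments tile each contig exactly, and a size-selection window plus
an end-type rule pick the subset that would enter the library. The default
enzyme pair is PstI (CTGCA^G) + MseI (T^TAA).

Cut coordinates are top-strand cleavage positions in 0-based contig
coordinates; sticky-end overhangs are ignored for fragment length, which is
the appropriate resolution for fragment-length distributions. Soft-masked
(lowercase) sequence is scanned normally — restriction enzymes cut repeats
too; masking only matters for the downstream flank filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import MaskedSequence

ENZ_A = "ENZ_A"
ENZ_B = "ENZ_B"
CONTIG_END = "CONTIG_END"

END_RULES = ("AB_ONLY", "ANY", "AA_ONLY", "BB_ONLY")


class DigestCollisionError(ValueError):
    """Both enzymes cleave at the same coordinate; end labels are ambiguous."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and top-strand cut offset.

    ``cut_offset`` is the position of the cleavage within the recognition
    site, so a site starting at 0-based ``s`` cuts at ``s + cut_offset``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or not set(self.recognition) <= set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition must be a non-empty A/C/G/T string"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside recognition site"
            )


# Canonical recognition sites and top-strand cleavage positions.
PSTI = Enzyme(name="PstI", recognition="CTGCAG", cut_offset=5)
MSEI = Enzyme(name="MseI", recognition="TTAA", cut_offset=1)
ENZYMES = {e.name: e for e in (PSTI, MSEI)}


@dataclass(frozen=True)
class Fragment:
    """A digestion interval, 0-based half-open, with labelled boundary types."""

    contig: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeWindow:
    """A fragment length window in bp.

    ``adapter_allowance`` is subtracted from both bounds before comparison,
    for windows quoted on adaptor-ligated molecules rather than inserts.
    """

    min_len: int
    max_len: int
    adapter_allowance: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_len <= self.max_len:
            raise ValueError(f"invalid size window [{self.min_len},{self.max_len}]")

    def contains(self, length: int) -> bool:
        return (
            self.min_len - self.adapter_allowance
            <= length
            <= self.max_len - self.adapter_allowance
        )


def find_cut_sites(seq: MaskedSequence, enzyme: Enzyme) -> list[int]:
    """All top-strand cut coordinates of ``enzyme`` on the plus strand.

    The scan is case-insensitive, reports overlapping occurrences, and never
    matches through N/n (they are not A/C/G/T).
    """
    text = seq.bases.upper()
    motif = enzyme.recognition
    cuts = []
    start = text.find(motif)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = text.find(motif, start + 1)
    return cuts


def digest(
    reference: Iterable[MaskedSequence], enzyme_a: Enzyme, enzyme_b: Enzyme
) -> list[Fragment]:
    """Double-digest ``reference``; fragments tile each contig exactly.

    The union of both enzymes' cut coordinates partitions each contig [0, L);
    every internal boundary is labelled by the enzyme that produced it and
    contig termini are labelled CONTIG_END. Cuts that fall exactly on a
    contig terminus are dropped (they produce no internal boundary). A
    coordinate cut by both enzymes has no well-defined label and raises
    :class:`DigestCollisionError`.
    """
    if enzyme_a == enzyme_b:
        raise ValueError("digest requires two distinct enzymes")
    fragments: list[Fragment] = []
    for seq in reference:
        length = len(seq)
        cuts_a = {c for c in find_cut_sites(seq, enzyme_a) if 0 < c < length}
        cuts_b = {c for c in find_cut_sites(seq, enzyme_b) if 0 < c < length}
        clash = cuts_a & cuts_b
        if clash:
            raise DigestCollisionError(
                f"{seq.name}: both enzymes cut at {sorted(clash)[0]}"
            )
        labelled = [(0, CONTIG_END)]
        labelled += sorted(
            [(c, ENZ_A) for c in cuts_a] + [(c, ENZ_B) for c in cuts_b]
        )
        labelled.append((length, CONTIG_END))
        for (start, left_label), (end, right_label) in zip(labelled, labelled[1:]):
            fragments.append(
                Fragment(
                    contig=seq.name,
                    start=start,
                    end=end,
                    left_end=left_label,
                    right_end=right_label,
                )
            )
    return fragments


def select_fragments(
    fragments: Iterable[Fragment], window: SizeWindow, end_rule: str = "AB_ONLY"
) -> list[Fragment]:
    """Apply size selection and an end-type rule.

    AB_ONLY keeps fragments with one end from each enzyme (either
    orientation) — the standard ddRAD adapter chemistry; AA_ONLY/BB_ONLY keep
    same-enzyme ends; ANY ignores end types. Fragments touching a contig
    terminus never satisfy AB_ONLY/AA_ONLY/BB_ONLY.
    """
    if end_rule not in END_RULES:
        raise ValueError(f"end_rule must be one of {END_RULES}, got {end_rule!r}")
    wanted = {
        "AB_ONLY": {frozenset({ENZ_A, ENZ_B})},
        "AA_ONLY": {frozenset({ENZ_A})},
        "BB_ONLY": {frozenset({ENZ_B})},
    }
    selected = []
    for frag in fragments:
        if not window.contains(frag.length):
            continue
        if end_rule != "ANY":
            ends = frozenset({frag.left_end, frag.right_end})
            if CONTIG_END in ends or ends not in wanted[end_rule]:
                continue
        selected.append(frag)
    return selected


def length_histogram(fragments: Iterable[Fragment], bin_width: int) -> dict[int, int]:
    """Fragment counts per half-open length bin [k*w, (k+1)*w), keyed by k*w."""
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    counts: Counter[int] = Counter()
    for frag in fragments:
        counts[(frag.length // bin_width) * bin_width] += 1
    return dict(sorted(counts.items()))


def fragments_to_frame(fragments: Sequence[Fragment]) -> pd.DataFrame:
    """Tabulate fragments (contig, start, end, left_end, right_end, length)."""
    return pd.DataFrame(
        [
            {
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "left_end": f.left_end,
                "right_end": f.right_end,
                "length": f.length,
            }
            for f in fragments
        ],
        columns=["contig", "start", "end", "left_end", "right_end", "length"],
    )


def write_fragments_bed(fragments: Sequence[Fragment], path) -> None:
    """Write fragments as BED intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.left_end}-{f.right_end}\n")
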