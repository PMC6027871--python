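"""Readers and writers for the formats the pipeline touches.

Dialects are deliberately minimal: VCF v4.2 with a GT-only FORMAT (the shape
of a STACKS ``populations`` export), case-preserving FASTA where lowercase
marks soft-masked repeat sequence, the two-column STACKS-style popmap, and a
marker table (TSV) with a companion BED of marker positions.

Coordinate conventions: VCF positions and marker-table positions are 1-based;
BED intervals and all internal fragment arithmetic are 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Genotype codes used in GenotypeMatrix.calls (int8).
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_VALID_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})
_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for malformed or unsupported VCF input."""


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


class PopMapError(ValueError):
    """Raised for malformed popmap input or unmapped individuals."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP site: contig, 1-based position, id, ref/alt base."""

    contig: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"{self.contig}:{self.pos}: alleles must be single bases "
                f"A/C/G/T, got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.pos}: ref == alt ({self.ref})")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites with genotype calls.

    ``calls`` holds int8 codes (HOM_REF/HET/HOM_ALT/MISSING) with shape
    ``(n_individuals, n_sites)``; column order matches ``sites`` and site
    positions are strictly increasing within each contig.
    """

    individuals: list[str]
    sites: list[SiteRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.sites)})"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        if self.calls.size and not set(np.unique(self.calls)) <= _VALID_CODES:
            bad = set(np.unique(self.calls)) - _VALID_CODES
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        for contig, group in itertools.groupby(self.sites, key=lambda s: s.contig):
            positions = [s.pos for s in group]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(
                    f"site positions not strictly increasing on contig {contig}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site columns (ordered)."""
        idx = list(indices)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=[self.sites[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )

    def individual_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.individuals)}


@dataclass
class PopMap:
    """Mapping individual -> group label (e.g. SK, WT, SW, WS)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise PopMapError("popmap is empty")

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [ind for ind, g in self.assignments.items() if g == group]

    def group_of(self, individual: str) -> str:
        try:
            return self.assignments[individual]
        except KeyError:
            raise PopMapError(f"individual {individual!r} missing from popmap")


@dataclass
class MaskedSequence:
    """A named sequence over {A,C,G,T,N,a,c,g,t,n}; lowercase = soft-masked."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class DiagnosticMarker:
    """A site passing the diagnostic screen, with species alleles and flanks."""

    site: SiteRecord
    allele_species_a: str
    allele_species_b: str
    flank_left: str
    flank_right: str
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.allele_species_a == self.allele_species_b:
            raise ValueError(f"{self.site.id}: species alleles are identical")
        for flank in (self.flank_left, self.flank_right):
            if not set(flank) <= _BASES:
                raise ValueError(
                    f"{self.site.id}: flank contains non-ACGT or masked bases"
                )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic, GT-only SNP VCF into a GenotypeMatrix.

    Genotypes are mapped 0/0 -> HOM_REF, 0/1 or 1/0 -> HET, 1/1 -> HOM_ALT and
    ./. -> MISSING; phased separators are accepted and treated as unphased.
    Multi-allelic or non-SNP records are rejected with their contig:pos.
    """
    path = Path(path)
    verbosity = pysam.set_verbosity(0)  # silence undefined-contig chatter
    try:
        try:
            vf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
        with vf:
            individuals = list(vf.header.samples)
            sites: list[SiteRecord] = []
            columns: list[np.ndarray] = []
            bad_records: list[str] = []
            for rec in vf:
                alts = rec.alts or ()
                if (
                    len(alts) != 1
                    or rec.ref is None
                    or len(rec.ref) != 1
                    or len(alts[0]) != 1
                    or rec.ref.upper() not in _BASES
                    or alts[0].upper() not in _BASES
                ):
                    bad_records.append(f"{rec.chrom}:{rec.pos}")
                    continue
                if "GT" not in (rec.format or {}):
                    raise VcfParseError(
                        f"{path}: record {rec.chrom}:{rec.pos} has no GT field"
                    )
                col = np.empty(len(individuals), dtype=np.int8)
                for i, sample in enumerate(rec.samples.values()):
                    gt = sample.get("GT")
                    if gt is None or any(a is None for a in gt):
                        col[i] = MISSING
                    elif len(gt) == 2 and set(gt) <= {0, 1}:
                        col[i] = gt[0] + gt[1]  # 0/0->0, 0/1|1/0->1, 1/1->2
                    else:
                        raise VcfParseError(
                            f"{path}: unsupported genotype {gt} at "
                            f"{rec.chrom}:{rec.pos}"
                        )
                sites.append(
                    SiteRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        id=rec.id or f"{rec.chrom}:{rec.pos}",
                        ref=rec.ref.upper(),
                        alt=alts[0].upper(),
                    )
                )
                columns.append(col)
            if bad_records:
                raise VcfParseError(
                    f"{path}: multi-allelic or non-SNP records not supported: "
                    + ", ".join(bad_records)
                )
    finally:
        pysam.set_verbosity(verbosity)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals=individuals, sites=sites, calls=calls)


_CODE_TO_GT = {
    HOM_REF: (0, 0),
    HET: (0, 1),  # canonical orientation, never 1/0
    HOM_ALT: (1, 1),
    MISSING: (None, None),
}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 with a GT-only FORMAT.

    QUAL/FILTER/INFO are emitted as missing; heterozygotes are written as the
    canonical ``0/1`` so that write/read round-trips are byte-stable.
    """
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    seen: dict[str, None] = {}
    for site in matrix.sites:
        seen.setdefault(site.contig)
    for contig in seen:
        header.contigs.add(contig)
    for name in matrix.individuals:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
                id=site.id,
            )
            for i, name in enumerate(matrix.individuals):
                rec.samples[name]["GT"] = _CODE_TO_GT[int(matrix.calls[i, j])]
            out.write(rec)


def read_fasta(path: str | Path) -> list[MaskedSequence]:
    """Read FASTA, preserving case; names are taken up to first whitespace."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    sequences = []
    names = set()
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        if rec.id in names:
            raise FastaParseError(f"{path}: duplicate contig name {rec.id!r}")
        names.add(rec.id)
        sequences.append(MaskedSequence(name=rec.id, bases=str(rec.seq)))
    return sequences


def write_fasta(sequences: Iterable[MaskedSequence], path: str | Path) -> None:
    """Write sequences as FASTA (case preserved, 60 columns)."""
    records = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_popmap(path: str | Path) -> PopMap:
    """Read a two-column ``individual<TAB>group`` popmap (no header).

    Blank lines and lines starting with ``#`` are ignored.
    """
    path = Path(path)
    assignments: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise PopMapError(
                f"{path}:{lineno}: expected 'individual<TAB>group', got {raw!r}"
            )
        individual, group = fields[0], fields[1]
        if individual in assignments:
            raise PopMapError(f"{path}:{lineno}: duplicate individual {individual!r}")
        assignments[individual] = group
    if not assignments:
        raise PopMapError(f"{path}: no assignments found")
    return PopMap(assignments=assignments)


def write_popmap(popmap: PopMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{ind}\t{grp}\n" for ind, grp in popmap.assignments.items())
    )


MARKER_COLUMNS = [
    "id",
    "contig",
    "pos",
    "allele_speciesA",
    "allele_speciesB",
    "flank_left",
    "flank_right",
]


def write_marker_table(
    markers: Sequence[DiagnosticMarker],
    path: str | Path,
    bed_path: str | Path | None = None,
) -> None:
    """Write a diagnostic-marker TSV plus a companion BED of marker positions.

    The TSV carries 1-based positions; the BED is 0-based half-open with one
    length-1 interval per marker. ``bed_path`` defaults to ``path`` with a
    ``.bed`` suffix.
    """
    path = Path(path)
    bed = Path(bed_path) if bed_path is not None else path.with_suffix(".bed")
    frame = pd.DataFrame(
        [
            {
                "id": m.site.id,
                "contig": m.site.contig,
                "pos": m.site.pos,
                "allele_speciesA": m.allele_species_a,
                "allele_speciesB": m.allele_species_b,
                "flank_left": m.flank_left,
                "flank_right": m.flank_right,
            }
            for m in markers
        ],
        columns=MARKER_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
    with open(bed, "w") as fh:
        for m in markers:
            fh.write(f"{m.site.contig}\t{m.site.pos - 1}\t{m.site.pos}\t{m.site.id}\n")


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker TSV written by :func:`write_marker_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"flank_left": str, "flank_right": str})
    missing = set(MARKER_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: marker table missing columns {sorted(missing)}")
    return frame
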