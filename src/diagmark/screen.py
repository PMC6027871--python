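"""The diagnostic-marker screen: fixed difference, obligate heterozygosity,
clean flanks.

A species-diagnostic SNP separates two hybridizing species: every individual
of species A is homozygous for one allele, every individual of species B
homozygous for the other, and — because an F1 hybrid carries one chromosome
from each species — every F1 is heterozygous. The screen applies these two
genotype criteria and then an assay-design filter: each side of the SNP must
offer ``flank_len`` (default 40) reference bases that are free of repeats
(soft-masked or N bases) and of any other known variant, and must not run off
the contig end.

Missing genotypes: the criteria are evaluated over *called* genotypes, gated
by a per-group minimum call rate (default 0.85, mirroring an upstream
85%-presence filter); ``require_no_missing=True`` switches to the strict
reading in which any missing call disqualifies the site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    DiagnosticMarker,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MaskedSequence,
    PopMap,
    SiteRecord,
)
from .popgen import _group_rows

logger = logging.getLogger(__name__)

STAGE_FIXED_DIFFERENCE = "fixed_difference"
STAGE_HYBRID_HET = "hybrid_het"
STAGE_FLANK = "flank"


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the three-stage diagnostic screen."""

    species_groups: tuple[str, str] = ("SK", "WT")
    hybrid_groups: tuple[str, ...] = ("SW", "WS")
    min_call_rate: float = 0.85
    require_no_missing: bool = False
    flank_len: int = 40

    def __post_init__(self) -> None:
        if self.species_groups[0] == self.species_groups[1]:
            raise ValueError("species groups must be distinct")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0,1]")


@dataclass(frozen=True)
class Candidate:
    """A site surviving the genotype screens, with species-allele assignment."""

    site_index: int
    site: SiteRecord
    allele_species_a: str
    allele_species_b: str
    n_called: dict[str, int] = field(default_factory=dict, compare=False)


@dataclass
class ScreenResult:
    markers: list[DiagnosticMarker]
    stage_counts: dict[str, int]


def _group_ok(block: np.ndarray) -> np.ndarray:
    """Per-site call rate for a group block (rows = its individuals)."""
    return (block != MISSING).sum(axis=0) / block.shape[0]


def fixed_difference_screen(
    matrix: GenotypeMatrix, popmap: PopMap, config: ScreenConfig = ScreenConfig()
) -> list[Candidate]:
    """Sites where the two species groups are fixed for alternate alleles.

    Every called individual of species A must be homozygous for one allele
    and every called individual of species B homozygous for the other; both
    groups must meet the call-rate gate (or carry no missing call at all
    under ``require_no_missing``).
    """
    rows = _group_rows(matrix, popmap)
    for g in config.species_groups:
        if g not in rows:
            raise ValueError(f"species group {g!r} has no individuals")
    a_block = matrix.calls[rows[config.species_groups[0]], :]
    b_block = matrix.calls[rows[config.species_groups[1]], :]

    def fixed_state(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(all-called-hom-ref, all-called-hom-alt), requiring >=1 call."""
        called = block != MISSING
        n_called = called.sum(axis=0)
        all_ref = ((block == HOM_REF) | ~called).all(axis=0) & (n_called > 0)
        all_alt = ((block == HOM_ALT) | ~called).all(axis=0) & (n_called > 0)
        return all_ref, all_alt

    a_ref, a_alt = fixed_state(a_block)
    b_ref, b_alt = fixed_state(b_block)
    gate = _call_rate_gate(a_block, config) & _call_rate_gate(b_block, config)
    keep_ref_alt = a_ref & b_alt & gate  # A fixed ref, B fixed alt
    keep_alt_ref = a_alt & b_ref & gate
    candidates = []
    for j in np.nonzero(keep_ref_alt | keep_alt_ref)[0]:
        site = matrix.sites[j]
        a_allele, b_allele = (
            (site.ref, site.alt) if keep_ref_alt[j] else (site.alt, site.ref)
        )
        candidates.append(
            Candidate(
                site_index=int(j),
                site=site,
                allele_species_a=a_allele,
                allele_species_b=b_allele,
                n_called={
                    config.species_groups[0]: int((a_block[:, j] != MISSING).sum()),
                    config.species_groups[1]: int((b_block[:, j] != MISSING).sum()),
                },
            )
        )
    return candidates


def _call_rate_gate(block: np.ndarray, config: ScreenConfig) -> np.ndarray:
    if config.require_no_missing:
        return (block != MISSING).all(axis=0)
    return _group_ok(block) >= config.min_call_rate


def hybrid_heterozygosity_screen(
    candidates: Sequence[Candidate],
    matrix: GenotypeMatrix,
    popmap: PopMap,
    config: ScreenConfig = ScreenConfig(),
) -> list[Candidate]:
    """Keep candidates where every called hybrid individual is heterozygous.

    Each hybrid group must independently satisfy the call-rate gate; over its
    called individuals observed heterozygosity must be exactly 1.
    """
    rows = _group_rows(matrix, popmap)
    for g in config.hybrid_groups:
        if g not in rows:
            raise ValueError(f"hybrid group {g!r} has no individuals")
    kept = []
    for cand in candidates:
        ok = True
        n_called = dict(cand.n_called)
        for g in config.hybrid_groups:
            col = matrix.calls[rows[g], cand.site_index]
            called = col != MISSING
            if not _call_rate_gate(col[:, None], config)[0]:
                ok = False
                break
            if called.sum() == 0 or not (col[called] == HET).all():
                ok = False
                break
            n_called[g] = int(called.sum())
        if ok:
            kept.append(
                Candidate(
                    site_index=cand.site_index,
                    site=cand.site,
                    allele_species_a=cand.allele_species_a,
                    allele_species_b=cand.allele_species_b,
                    n_called=n_called,
                )
            )
    return kept


def flank_filter(
    candidates: Sequence[Candidate],
    reference: Sequence[MaskedSequence],
    all_sites: Sequence[SiteRecord],
    config: ScreenConfig = ScreenConfig(),
) -> list[DiagnosticMarker]:
    """Retain candidates offering clean ``flank_len``-bp flanks on both sides.

    For a site at 1-based position P the flanks are reference bases
    [P-flank_len, P-1] and [P+1, P+flank_len]. A candidate is rejected when a
    flank would extend past a contig end, contains a soft-masked (lowercase)
    or N base, or overlaps the position of any *other* site in ``all_sites``.
    The uppercase reference base at P must equal the site's ref allele
    (flanks are retrieved from that reference; a mismatch signals coordinate
    slippage) — violations warn and reject.
    """
    by_name = {seq.name: seq for seq in reference}
    positions_by_contig: dict[str, np.ndarray] = {}
    for contig in {s.contig for s in all_sites}:
        positions_by_contig[contig] = np.asarray(
            sorted(s.pos for s in all_sites if s.contig == contig)
        )
    markers = []
    flank = config.flank_len
    for cand in candidates:
        site = cand.site
        if site.contig not in by_name:
            raise KeyError(f"contig {site.contig!r} absent from reference")
        seq = by_name[site.contig].bases
        p0 = site.pos - 1  # 0-based
        if p0 - flank < 0 or p0 + flank >= len(seq):
            continue
        base = seq[p0].upper()
        if base != site.ref:
            warnings.warn(
                f"{site.id} ({site.contig}:{site.pos}): reference base {base!r} "
                f"does not match ref allele {site.ref!r}; site rejected",
                stacklevel=2,
            )
            continue
        left = seq[p0 - flank : p0]
        right = seq[p0 + 1 : p0 + 1 + flank]
        if not (_clean(left) and _clean(right)):
            continue
        near = positions_by_contig[site.contig]
        lo = np.searchsorted(near, site.pos - flank, side="left")
        hi = np.searchsorted(near, site.pos + flank, side="right")
        # window [P-flank, P+flank] holds only the site itself
        if hi - lo != 1:
            continue
        markers.append(
            DiagnosticMarker(
                site=site,
                allele_species_a=cand.allele_species_a,
                allele_species_b=cand.allele_species_b,
                flank_left=left,
                flank_right=right,
                provenance={"n_called": dict(cand.n_called)},
            )
        )
    return markers


def _clean(flank: str) -> bool:
    return set(flank) <= set("ACGT")


def run_screen(
    matrix: GenotypeMatrix,
    popmap: PopMap,
    reference: Sequence[MaskedSequence],
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Compose the three screens; stage survivor counts are logged."""
    fixed = fixed_difference_screen(matrix, popmap, config)
    obligate = hybrid_heterozygosity_screen(fixed, matrix, popmap, config)
    markers = flank_filter(obligate, reference, matrix.sites, config)
    counts = {
        "input_sites": matrix.n_sites,
        STAGE_FIXED_DIFFERENCE: len(fixed),
        STAGE_HYBRID_HET: len(obligate),
        STAGE_FLANK: len(markers),
    }
    logger.info(
        "screen: %d sites -> %d fixed-different -> %d obligate-het -> %d markers",
        counts["input_sites"],
        len(fixed),
        len(obligate),
        len(markers),
    )
    return ScreenResult(markers=markers, stage_counts=counts)
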