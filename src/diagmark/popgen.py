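"""Per-site, per-group screening statistics and site filters.

For each biallelic site and each group the module computes sample allele
frequencies, call rate, observed heterozygosity Hobs (fraction of called
individuals that are heterozygous), expected heterozygosity Hexp = 2*p*q from
the sample allele frequency, and the inbreeding coefficient

    FIS = (Hexp - Hobs) / Hexp,   defined as 0 when Hexp = 0.

No small-sample correction is applied to Hexp; this is the plain 2pq
estimator, which differs from pi-based estimators (e.g. STACKS) by a factor
of order 1/(2n). Negative FIS marks heterozygote excess — the signature of
interspecific hybrids at sites differentiated between the parental species.

Site filters mirror a STACKS ``populations`` run with ``-p`` / ``-r`` /
``--min_maf``: a site is kept when at least ``min_populations`` groups reach
the per-group call-rate threshold and the pooled minor allele frequency over
all called alleles (across every group) reaches ``min_maf``. The pooled-MAF
convention is a documented choice; per-group frequencies are reported
alongside so the per-population convention can be checked externally.

An allele is *private* to a group when its count is non-zero in that group
and zero in every other group, over called genotypes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HET, HOM_ALT, MISSING, PopMap, PopMapError


@dataclass(frozen=True)
class FilterConfig:
    """Site-retention thresholds (defaults match ``-p 4 -r 0.85 --min_maf 0.1``)."""

    min_populations: int = 4
    min_fraction_per_pop: float = 0.85
    min_maf: float = 0.1

    def __post_init__(self) -> None:
        if self.min_populations < 1:
            raise ValueError("min_populations must be >= 1")
        if not 0 <= self.min_fraction_per_pop <= 1:
            raise ValueError("min_fraction_per_pop must be in [0,1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0,0.5]")


@dataclass
class SiteStatsTable:
    """Per-(site, group) statistics plus pooled per-site columns.

    ``per_group`` has one row per site x group: n_called, call_rate, p_ref,
    p_alt, hobs, hexp, fis, low_confidence (fewer than 2 called individuals;
    statistics still computed, never silently zeroed — groups with no calls
    carry NaN). ``pooled`` has one row per site: pooled alt frequency, MAF
    over all called alleles, and the private-allele attribution (group label
    and allele, or missing).
    """

    per_group: pd.DataFrame
    pooled: pd.DataFrame

    def merged(self) -> pd.DataFrame:
        """Long table: per-group rows joined with the pooled site columns."""
        return self.per_group.merge(
            self.pooled.drop(columns=["contig", "pos"]), on="site_id", how="left"
        )


def _group_rows(matrix: GenotypeMatrix, popmap: PopMap) -> dict[str, np.ndarray]:
    """Row indices per group; every individual must be mapped."""
    index = matrix.individual_index()
    unmapped = [ind for ind in matrix.individuals if ind not in popmap.assignments]
    if unmapped:
        raise PopMapError(f"individuals missing from popmap: {unmapped}")
    rows: dict[str, list[int]] = {}
    for ind in matrix.individuals:
        rows.setdefault(popmap.assignments[ind], []).append(index[ind])
    return {g: np.asarray(r, dtype=int) for g, r in rows.items()}


def _tally(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, n_het, alt_allele_count) per site for a block of rows."""
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    alt_count = n_het + 2 * (calls == HOM_ALT).sum(axis=0)
    return n_called, n_het, alt_count


def site_stats(matrix: GenotypeMatrix, popmap: PopMap) -> SiteStatsTable:
    """Compute per-group and pooled statistics for every site.

    Statistics use called genotypes only. FIS is 0 where Hexp = 0 (monomorphic
    sample); groups with zero called individuals get NaN, never silent zeros.
    """
    groups = popmap.groups
    rows = _group_rows(matrix, popmap)
    site_ids = [s.id for s in matrix.sites]
    contigs = [s.contig for s in matrix.sites]
    positions = [s.pos for s in matrix.sites]

    per_group_frames = []
    group_alt_counts: dict[str, np.ndarray] = {}
    group_called: dict[str, np.ndarray] = {}
    for group in groups:
        block = matrix.calls[rows[group], :]
        n_in_group = len(rows[group])
        n_called, n_het, alt_count = _tally(block)
        group_alt_counts[group] = alt_count
        group_called[group] = n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_called > 0, alt_count / (2 * n_called), np.nan)
            hobs = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        p_ref = 1.0 - p_alt
        hexp = 2.0 * p_ref * p_alt
        fis = np.where(
            np.nan_to_num(hexp) > 0,
            (hexp - hobs) / np.where(hexp > 0, hexp, 1.0),
            np.where(np.isnan(hexp), np.nan, 0.0),
        )
        per_group_frames.append(
            pd.DataFrame(
                {
                    "site_id": site_ids,
                    "contig": contigs,
                    "pos": positions,
                    "group": group,
                    "n_called": n_called,
                    "call_rate": n_called / n_in_group,
                    "p_ref": p_ref,
                    "p_alt": p_alt,
                    "hobs": hobs,
                    "hexp": hexp,
                    "fis": fis,
                    "low_confidence": n_called < 2,
                }
            )
        )
    per_group = pd.concat(per_group_frames, ignore_index=True)

    total_alt = np.sum([group_alt_counts[g] for g in groups], axis=0)
    total_called = np.sum([group_called[g] for g in groups], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_p_alt = np.where(total_called > 0, total_alt / (2 * total_called), np.nan)
    maf = np.minimum(pooled_p_alt, 1.0 - pooled_p_alt)

    private_group, private_allele = _private_attribution(
        groups, group_alt_counts, group_called
    )
    pooled = pd.DataFrame(
        {
            "site_id": site_ids,
            "contig": contigs,
            "pos": positions,
            "n_called_total": total_called,
            "p_alt_pooled": pooled_p_alt,
            "maf": maf,
            "private_group": private_group,
            "private_allele": private_allele,
        }
    )
    return SiteStatsTable(per_group=per_group, pooled=pooled)


def _private_attribution(
    groups: Sequence[str],
    group_alt_counts: dict[str, np.ndarray],
    group_called: dict[str, np.ndarray],
) -> tuple[list, list]:
    """Per-site private-allele attribution over called genotypes.

    Checks both alleles: an allele is private to group g iff its count is > 0
    in g and 0 in every other group. At most one allele can be private to at
    most one group at a biallelic site with >= 2 groups carrying calls.
    """
    n_sites = len(next(iter(group_alt_counts.values()))) if group_alt_counts else 0
    alt = np.stack([group_alt_counts[g] for g in groups])  # groups x sites
    ref = np.stack(
        [2 * group_called[g] - group_alt_counts[g] for g in groups]
    )
    private_group: list = [None] * n_sites
    private_allele: list = [None] * n_sites
    for counts, allele_label in ((alt, "alt"), (ref, "ref")):
        carriers = counts > 0
        n_carrier_groups = carriers.sum(axis=0)
        for j in np.nonzero(n_carrier_groups == 1)[0]:
            g = groups[int(np.nonzero(carriers[:, j])[0][0])]
            private_group[j] = g
            private_allele[j] = allele_label
    return private_group, private_allele


def apply_site_filters(
    matrix: GenotypeMatrix, popmap: PopMap, config: FilterConfig = FilterConfig()
) -> GenotypeMatrix:
    """Retain sites passing the group call-rate and pooled-MAF filters.

    A site is kept when at least ``min_populations`` groups have call rate
    >= ``min_fraction_per_pop`` and the pooled MAF is >= ``min_maf``. Site
    order is preserved.
    """
    stats = site_stats(matrix, popmap)
    n_groups = len(popmap.groups)
    n_sites = matrix.n_sites
    # per_group rows are group-major blocks in site order
    call_rate = stats.per_group["call_rate"].to_numpy().reshape(n_groups, n_sites)
    ok_groups = (call_rate >= config.min_fraction_per_pop).sum(axis=0)
    maf = np.nan_to_num(stats.pooled["maf"].to_numpy(), nan=0.0)
    keep = np.nonzero(
        (ok_groups >= config.min_populations) & (maf >= config.min_maf)
    )[0]
    return matrix.subset_sites(keep.tolist())


def private_alleles(
    matrix: GenotypeMatrix, popmap: PopMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Private alleles per group.

    Returns ``(sites, summary)``: ``sites`` has one row per private-allele
    site (site_id, contig, pos, group, allele base, frequency of the private
    allele within its group, pooled MAF); ``summary`` has one row per group
    with the site count, mean in-group private-allele frequency and mean
    pooled MAF of its private sites.
    """
    if len(popmap.groups) < 2:
        raise ValueError("private alleles need at least 2 groups")
    stats = site_stats(matrix, popmap)
    pooled = stats.pooled
    groups = popmap.groups
    n_sites = matrix.n_sites
    # per-group p_alt as a (group -> site-ordered array) lookup
    p_alt_all = stats.per_group["p_alt"].to_numpy().reshape(len(groups), n_sites)
    group_row = {g: i for i, g in enumerate(groups)}
    records = []
    mask = pooled["private_group"].notna()
    for j, row in pooled[mask].iterrows():
        site = matrix.sites[j]
        group = row["private_group"]
        which = row["private_allele"]
        p_alt = p_alt_all[group_row[group], j]
        records.append(
            {
                "site_id": row["site_id"],
                "contig": site.contig,
                "pos": site.pos,
                "group": group,
                "allele": site.alt if which == "alt" else site.ref,
                "freq_in_group": p_alt if which == "alt" else 1.0 - p_alt,
                "maf_pooled": row["maf"],
            }
        )
    sites = pd.DataFrame(
        records,
        columns=[
            "site_id",
            "contig",
            "pos",
            "group",
            "allele",
            "freq_in_group",
            "maf_pooled",
        ],
    )
    if len(sites):
        summary = (
            sites.groupby("group")
            .agg(
                n_sites=("site_id", "size"),
                mean_freq_in_group=("freq_in_group", "mean"),
                mean_maf_pooled=("maf_pooled", "mean"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["group", "n_sites", "mean_freq_in_group", "mean_maf_pooled"]
        )
    return sites, summary
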