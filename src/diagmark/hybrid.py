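"""Hybrid-index scoring and hybrid-class assignment on a diagnostic panel.

At a species-diagnostic locus the genotype of any individual is AA, AB or BB,
where A and B are the alleles fixed in the two parental species. Over a panel
of such loci:

* hybrid index ``h`` — the fraction of species-B alleles among typed alleles
  (0 for pure A, 1 for pure B, 0.5 for F1), with a 95% Wilson interval that
  treats the ``2 * n_typed`` alleles as independent draws (markers are
  genome-wide and unlinked by design intent; the interval is approximate);
* interspecific heterozygosity ``H_inter`` — the fraction of typed markers
  that are heterozygous;
* a maximum-likelihood assignment to one of the six canonical first- and
  second-generation classes via the Mendelian genotype expectations

      PURE_A (1,0,0)   PURE_B (0,0,1)   F1 (0,1,0)
      F2 (1/4,1/2,1/4) BC_A (1/2,1/2,0) BC_B (0,1/2,1/2)

  mixed with a per-genotype miscall rate ``(1-e)*model + e*uniform`` so that
  pure classes keep finite likelihood under occasional genotyping error.
  Later-generation hybrids map onto the nearest of these classes; separating
  them needs linkage information a fixed-difference panel does not carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

CLASS_ORDER = ("PURE_A", "PURE_B", "F1", "F2", "BC_A", "BC_B")

# Expected (AA, AB, BB) genotype probabilities at a diagnostic locus.
_BASE_PROBS = {
    "PURE_A": (1.0, 0.0, 0.0),
    "PURE_B": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_A": (0.5, 0.5, 0.0),
    "BC_B": (0.0, 0.5, 0.5),
}

_SWAP = {
    "PURE_A": "PURE_B",
    "PURE_B": "PURE_A",
    "F1": "F1",
    "F2": "F2",
    "BC_A": "BC_B",
    "BC_B": "BC_A",
}


@dataclass(frozen=True)
class ClassModel:
    """Error-mixed genotype probabilities for the six canonical classes."""

    error: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.error < 1:
            raise ValueError("error must be in [0,1)")

    def probs(self, class_name: str) -> np.ndarray:
        base = np.asarray(_BASE_PROBS[class_name])
        return (1.0 - self.error) * base + self.error / 3.0


@dataclass
class HybridReport:
    """Per-individual scores on a diagnostic panel."""

    individual: str
    n_typed: int
    h: float
    h_ci: tuple[float, float]
    h_inter: float
    class_call: str | None
    tie: bool
    log_likelihoods: dict[str, float] = field(default_factory=dict)


def score_individual(
    genotypes: Iterable[int],
    model: ClassModel = ClassModel(),
    individual: str = "query",
) -> HybridReport:
    """Score one individual from species-oriented genotype codes.

    ``genotypes`` are counts of species-B alleles per marker: 0 (AA),
    1 (AB), 2 (BB), or MISSING (-1). With zero typed markers every statistic
    is NaN and no class is called.
    """
    g = np.asarray(list(genotypes), dtype=int)
    typed = g[g != MISSING]
    n_typed = typed.size
    if n_typed == 0:
        return HybridReport(
            individual=individual,
            n_typed=0,
            h=math.nan,
            h_ci=(math.nan, math.nan),
            h_inter=math.nan,
            class_call=None,
            tie=False,
        )
    counts = np.bincount(typed, minlength=3)  # (n_AA, n_AB, n_BB)
    b_alleles = int(counts[1] + 2 * counts[2])
    n_alleles = 2 * n_typed
    h = b_alleles / n_alleles
    lo, hi = proportion_confint(b_alleles, n_alleles, alpha=0.05, method="wilson")
    h_inter = counts[1] / n_typed
    logliks: dict[str, float] = {}
    for name in CLASS_ORDER:
        with np.errstate(divide="ignore"):
            logp = np.log(model.probs(name))
        ll = float(np.dot(counts, np.where(counts > 0, logp, 0.0)))
        logliks[name] = ll
    best = max(logliks.values())
    winners = [c for c in CLASS_ORDER if logliks[c] >= best - 1e-9]
    return HybridReport(
        individual=individual,
        n_typed=int(n_typed),
        h=h,
        h_ci=(float(lo), float(hi)),
        h_inter=float(h_inter),
        class_call=winners[0],  # ties broken by fixed class order
        tie=len(winners) > 1,
        log_likelihoods=logliks,
    )


def orient_panel_calls(
    matrix: GenotypeMatrix, markers: pd.DataFrame
) -> np.ndarray:
    """Re-code VCF-oriented genotype calls as species-B allele counts.

    ``markers`` is a marker table (as written by ``write_marker_table``) whose
    rows are matched to matrix sites by (contig, pos). At markers where the
    species-A allele is the VCF alt allele, hom-ref and hom-alt swap.
    Matrix sites absent from the table are dropped; a marker absent from the
    matrix is ignored (the panel may exceed the genotyped subset).
    """
    panel = {
        (row.contig, int(row.pos)): (row.allele_speciesA, row.allele_speciesB)
        for row in markers.itertuples()
    }
    cols = []
    flip = []
    for j, site in enumerate(matrix.sites):
        key = (site.contig, site.pos)
        if key not in panel:
            continue
        allele_a, allele_b = panel[key]
        if allele_a == site.ref and allele_b == site.alt:
            flip.append(False)
        elif allele_a == site.alt and allele_b == site.ref:
            flip.append(True)
        else:
            raise ValueError(
                f"marker at {site.contig}:{site.pos} has alleles "
                f"{allele_a}/{allele_b} but site has {site.ref}/{site.alt}"
            )
        cols.append(j)
    calls = matrix.calls[:, cols].astype(int)
    flip_arr = np.asarray(flip, dtype=bool)
    oriented = calls.copy()
    if flip_arr.any():
        sub = calls[:, flip_arr]
        swapped = sub.copy()
        swapped[sub == HOM_REF] = HOM_ALT
        swapped[sub == HOM_ALT] = HOM_REF
        oriented[:, flip_arr] = swapped
    oriented[calls == MISSING] = MISSING
    return oriented


def score_cohort(
    matrix: GenotypeMatrix,
    markers: pd.DataFrame,
    model: ClassModel = ClassModel(),
) -> list[HybridReport]:
    """Score every individual in ``matrix`` against a marker panel."""
    oriented = orient_panel_calls(matrix, markers)
    return [
        score_individual(oriented[i, :], model, individual=name)
        for i, name in enumerate(matrix.individuals)
    ]


def reports_to_frame(reports: Sequence[HybridReport]) -> pd.DataFrame:
    """Tabulate reports; class counts are summarized via value_counts."""
    return pd.DataFrame(
        [
            {
                "individual": r.individual,
                "n_typed": r.n_typed,
                "h": r.h,
                "h_ci_low": r.h_ci[0],
                "h_ci_high": r.h_ci[1],
                "h_inter": r.h_inter,
                "class_call": r.class_call,
                "tie": r.tie,
                **{f"ll_{c}": r.log_likelihoods.get(c, math.nan) for c in CLASS_ORDER},
            }
            for r in reports
        ]
    )


def swap_species(report: HybridReport) -> HybridReport:
    """The report obtained by exchanging the species labels (h -> 1-h)."""
    return HybridReport(
        individual=report.individual,
        n_typed=report.n_typed,
        h=1.0 - report.h if not math.isnan(report.h) else report.h,
        h_ci=(1.0 - report.h_ci[1], 1.0 - report.h_ci[0]),
        h_inter=report.h_inter,
        class_call=None if report.class_call is None else _SWAP[report.class_call],
        tie=report.tie,
        log_likelihoods={_SWAP[c]: ll for c, ll in report.log_likelihoods.items()},
    )


def simulate_class_genotypes(
    class_name: str,
    n_markers: int,
    rng: np.random.Generator,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Draw oriented panel genotypes for an individual of a known class.

    Genotypes are sampled from the class's Mendelian expectations; with
    probability ``miscall_rate`` a call is replaced by one of the two other
    genotypes (uniformly), then masked missing with ``missing_rate``.
    """
    probs = np.asarray(_BASE_PROBS[class_name])
    g = rng.choice(3, size=n_markers, p=probs)
    if miscall_rate > 0:
        miscalled = rng.random(n_markers) < miscall_rate
        shift = rng.integers(1, 3, size=n_markers)
        g = np.where(miscalled, (g + shift) % 3, g)
    if missing_rate > 0:
        g = np.where(rng.random(n_markers) < missing_rate, MISSING, g)
    return g.astype(int)
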