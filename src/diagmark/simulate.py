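"""Synthetic ddRAD-style genotype data with a known truth table.

The generator emulates the sampling design of a two-species hybridization
panel: two parental species groups (default sizes 7 and 6) and two
reciprocal-cross F1 groups (9 and 8; 30 individuals in total), genotyped at a
mix of planted site categories on a toy soft-masked reference contig:

* ``diagnostic_clean`` — fixed for alternate alleles in the two species with
  clean 40-bp flanks: the sites the downstream screen must recover;
* five confounder categories, each deliberately failing exactly one screen
  clause: a second variant inside the 40-bp flank, a soft-masked flank base,
  a position too close to the contig edge, one non-heterozygous hybrid, one
  non-fixed parental individual;
* ``shared`` — polymorphic in both species, species-specific alt-allele
  frequencies drawn uniformly from ``maf_range``, genotypes sampled with a
  parental inbreeding coefficient ``fis_parental`` (captive herds descend
  from few founders and show a mild heterozygote deficit; this also gives
  the parental groups their positive mean FIS);
* ``private`` — an allele observed in exactly one group, at a target in-group
  frequency of 0.19, emulating rare variants private to a sampled group.

F1 genotypes are formed gamete-wise — one allele drawn from each parental
species' frequency — because the sampled parental individuals are *not* the
parents of the sampled hybrids. Genotyping error (symmetric miscall) and
missingness are applied last, in that order. All randomness flows from a
single seed through two spawned streams (reference, then genotypes) with a
fixed per-site draw order, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MaskedSequence,
    PopMap,
    SiteRecord,
)
from .screen import STAGE_FIXED_DIFFERENCE, STAGE_FLANK, STAGE_HYBRID_HET

CONFOUNDER_KINDS = (
    "flank_variant",
    "masked_flank",
    "contig_edge",
    "non_het_hybrid",
    "non_fixed_parental",
)

#: Screen stage at which each planted category is expected to fall out.
EXPECTED_FAIL_STAGE = {
    "diagnostic_clean": None,
    "flank_variant": STAGE_FLANK,
    "masked_flank": STAGE_FLANK,
    "contig_edge": STAGE_FLANK,
    "non_het_hybrid": STAGE_HYBRID_HET,
    "non_fixed_parental": STAGE_FIXED_DIFFERENCE,
    "shared": STAGE_FIXED_DIFFERENCE,
    "private": STAGE_FIXED_DIFFERENCE,
}

_MASK_RUN_LEN = 150
_SLOT_SPACING = 100


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the sampled design: group sizes (7, 6, 9, 8) for the
    two species and the two reciprocal F1 groups, 50 clean diagnostic sites,
    25 confounders (5 per failure mode), 400 shared polymorphic sites and 10
    group-private sites per group at a target in-group frequency of 0.19.
    """

    seed: int = 0
    n_per_group: tuple[int, int, int, int] = (7, 6, 9, 8)
    group_labels: tuple[str, str, str, str] = ("SK", "WT", "SW", "WS")
    n_diagnostic_clean: int = 50
    n_diagnostic_confounded: int = 25
    n_shared: int = 400
    n_private_per_group: tuple[int, int, int, int] = (10, 10, 10, 10)
    maf_range: tuple[float, float] = (0.1, 0.5)
    private_freq: float = 0.19
    fis_parental: float = 0.15
    missing_rate: float = 0.0
    genotyping_error: float = 0.0
    contig_length: int = 70_000
    mask_fraction: float = 0.08
    contig_name: str = "contig_1"
    flank_len: int = 40

    def __post_init__(self) -> None:
        counts = (
            self.n_diagnostic_clean,
            self.n_diagnostic_confounded,
            self.n_shared,
            *self.n_private_per_group,
            *self.n_per_group,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for p in (
            self.missing_rate,
            self.genotyping_error,
            self.mask_fraction,
            self.private_freq,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.contig_length < 200:
            raise ValueError("contig_length must be >= 200")
        if not -1 <= self.fis_parental < 1:
            raise ValueError("fis_parental must lie in [-1,1)")

    @property
    def n_sites(self) -> int:
        return (
            self.n_diagnostic_clean
            + self.n_diagnostic_confounded
            + self.n_shared
            + sum(self.n_private_per_group)
        )

    def confounder_counts(self) -> dict[str, int]:
        """Distribute confounders round-robin over the five failure modes."""
        base, extra = divmod(self.n_diagnostic_confounded, len(CONFOUNDER_KINDS))
        return {
            kind: base + (1 if i < extra else 0)
            for i, kind in enumerate(CONFOUNDER_KINDS)
        }


@dataclass
class SimResult:
    reference: list[MaskedSequence]
    matrix: GenotypeMatrix
    popmap: PopMap
    truth: pd.DataFrame


def _streams(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ref_ss, geno_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(ref_ss), np.random.default_rng(geno_ss)


def make_reference(config: SimConfig) -> list[MaskedSequence]:
    """A random contig with the configured fraction of soft-masked runs."""
    rng, _ = _streams(config)
    bases = rng.choice(list("ACGT"), size=config.contig_length)
    if config.mask_fraction >= 1.0:
        masked = np.char.lower(bases)
        return [MaskedSequence(config.contig_name, "".join(masked))]
    target = config.mask_fraction * config.contig_length
    n_runs = int(round(target / _MASK_RUN_LEN))
    seq = bases.copy()
    if n_runs > 0:
        starts = rng.integers(0, config.contig_length, size=n_runs)
        for s in sorted(starts.tolist()):
            seq[s : s + _MASK_RUN_LEN] = np.char.lower(seq[s : s + _MASK_RUN_LEN])
    return [MaskedSequence(config.contig_name, "".join(seq))]


def _window_clean(bases: str, pos: int, flank: int) -> bool:
    """True when the site base and both flanks are uppercase A/C/G/T.

    ``pos`` is 1-based; the window is [pos-flank, pos+flank].
    """
    lo, hi = pos - 1 - flank, pos + flank
    if lo < 0 or hi > len(bases):
        return False
    return set(bases[lo:hi]) <= set("ACGT")


def _plan_positions(
    config: SimConfig, bases: str
) -> list[tuple[int, str, str | None]]:
    """Assign a 1-based position to every planted site.

    Returns (pos, category, owner_group) tuples. Slots are spaced so that
    non-confounded sites never fall within each other's flanks; flank-variant
    confounders get a companion shared site exactly ``flank_len`` bp away,
    and contig-edge confounders sit within ``flank_len`` bp of the contig
    start. Raises when the contig cannot host the requested density.
    """
    flank = config.flank_len
    conf = config.confounder_counts()
    planned: list[tuple[int, str, str | None]] = []

    n_edge = conf["contig_edge"]
    edge_positions = [flank // 2 + 4 * k for k in range(n_edge)]
    if any(p > flank for p in edge_positions):
        raise ValueError(
            f"cannot place {n_edge} contig-edge confounders within "
            f"{flank} bp of the contig start"
        )
    planned += [(p, "contig_edge", None) for p in edge_positions]

    first_slot = 2 * flank + _SLOT_SPACING
    slots = list(range(first_slot, len(bases) - 2 * flank, _SLOT_SPACING))
    clean_slots = [p for p in slots if _window_clean(bases, p, flank)]
    other_slots = [p for p in slots if not _window_clean(bases, p, flank)]

    def take_clean(n: int, category: str) -> list[int]:
        if len(clean_slots) < n:
            raise ValueError(
                f"placement impossible: need {n} clean-flank slots for "
                f"{category}, only {len(clean_slots)} left"
            )
        taken, clean_slots[:n] = clean_slots[:n], []
        return taken

    # categories that must start from a clean-flank slot
    for category, count in (
        ("diagnostic_clean", config.n_diagnostic_clean),
        ("flank_variant", conf["flank_variant"]),
        ("masked_flank", conf["masked_flank"]),
        ("non_het_hybrid", conf["non_het_hybrid"]),
        ("non_fixed_parental", conf["non_fixed_parental"]),
    ):
        for p in take_clean(count, category):
            planned.append((p, category, None))
            if category == "flank_variant":
                planned.append((p + flank, "shared", None))

    n_companions = conf["flank_variant"]
    if config.n_shared < n_companions:
        raise ValueError(
            "n_shared must cover the flank-variant companion sites "
            f"({n_companions})"
        )
    remaining = sorted(clean_slots + other_slots)
    needed = (config.n_shared - n_companions) + sum(config.n_private_per_group)
    if len(remaining) < needed:
        raise ValueError(
            f"placement impossible: {needed} more sites requested but only "
            f"{len(remaining)} slots remain on {len(bases)} bp"
        )
    cursor = 0
    for _ in range(config.n_shared - n_companions):
        planned.append((remaining[cursor], "shared", None))
        cursor += 1
    for label, count in zip(config.group_labels, config.n_private_per_group):
        for _ in range(count):
            planned.append((remaining[cursor], "private", label))
            cursor += 1
    planned.sort(key=lambda t: t[0])
    return planned


def _hwe_probs(p_alt: float, fis: float) -> np.ndarray:
    q = 1.0 - p_alt
    pq = p_alt * q
    return np.asarray(
        [q * q + fis * pq, 2.0 * pq * (1.0 - fis), p_alt * p_alt + fis * pq]
    )


def simulate_genotypes(
    config: SimConfig, reference: list[MaskedSequence]
) -> tuple[GenotypeMatrix, PopMap, pd.DataFrame]:
    """Plant sites on ``reference`` and draw genotypes for every group.

    Masked-flank confounders are created by soft-masking one flank base of
    the supplied reference **in place**. The returned truth table has one row
    per planted site with its category, the species alleles where defined,
    the private-allele owner where applicable, and the expected screen
    verdict (pass / fail + failing stage) under zero error and missingness.
    """
    _, rng = _streams(config)
    seq = reference[0]
    bases = list(seq.bases)
    planned = _plan_positions(config, seq.bases)

    labels = config.group_labels
    individuals: list[str] = []
    assignments: dict[str, str] = {}
    for label, count in zip(labels, config.n_per_group):
        for i in range(count):
            name = f"{label}{i + 1}"
            individuals.append(name)
            assignments[name] = label
    popmap = PopMap(assignments=assignments)
    group_rows = {
        label: np.asarray([i for i, ind in enumerate(individuals)
                           if assignments[ind] == label])
        for label in labels
    }
    species_a, species_b = labels[0], labels[1]
    hybrid_labels = labels[2:]
    hybrid_rows = np.concatenate([group_rows[g] for g in hybrid_labels])

    n_ind = len(individuals)
    n_sites = len(planned)
    calls = np.full((n_ind, n_sites), MISSING, dtype=np.int8)
    sites: list[SiteRecord] = []
    truth_rows: list[dict] = []
    others = "ACGT"

    for j, (pos, category, owner) in enumerate(planned):
        base = bases[pos - 1].upper()
        if base not in "ACGT":
            raise ValueError(f"reference base at {pos} is not A/C/G/T")
        ref = base
        alt = rng.choice([b for b in others if b != ref])
        site_id = f"snp_{j + 1:05d}"
        sites.append(
            SiteRecord(contig=seq.name, pos=pos, id=site_id, ref=ref, alt=str(alt))
        )
        col = calls[:, j]
        allele_a = allele_b = None
        if category in (
            "diagnostic_clean",
            "flank_variant",
            "masked_flank",
            "contig_edge",
            "non_het_hybrid",
            "non_fixed_parental",
        ):
            col[group_rows[species_a]] = HOM_REF
            col[group_rows[species_b]] = HOM_ALT
            col[hybrid_rows] = HET
            allele_a, allele_b = ref, str(alt)
            if category == "masked_flank":
                k = pos - 1 + 10  # 0-based: 10 bp into the right flank
                bases[k] = bases[k].lower()
            elif category == "non_het_hybrid":
                victim = int(rng.choice(hybrid_rows))
                col[victim] = int(rng.choice([HOM_REF, HOM_ALT]))
            elif category == "non_fixed_parental":
                which = species_a if rng.random() < 0.5 else species_b
                victim = int(rng.choice(group_rows[which]))
                col[victim] = HET
        elif category == "shared":
            p_a = rng.uniform(*config.maf_range)
            p_b = rng.uniform(*config.maf_range)
            col[group_rows[species_a]] = rng.choice(
                3, size=len(group_rows[species_a]),
                p=_hwe_probs(p_a, config.fis_parental),
            )
            col[group_rows[species_b]] = rng.choice(
                3, size=len(group_rows[species_b]),
                p=_hwe_probs(p_b, config.fis_parental),
            )
            gam_a = rng.random(len(hybrid_rows)) < p_a
            gam_b = rng.random(len(hybrid_rows)) < p_b
            col[hybrid_rows] = gam_a.astype(int) + gam_b.astype(int)
        elif category == "private":
            fis = config.fis_parental if owner in (species_a, species_b) else 0.0
            probs = _hwe_probs(config.private_freq, fis)
            rows = group_rows[owner]
            for _attempt in range(1000):
                draw = rng.choice(3, size=len(rows), p=probs)
                if (draw > 0).any():  # condition on the allele being observed
                    break
            else:
                raise RuntimeError("could not realize a private allele in 1000 draws")
            col[:] = HOM_REF
            col[rows] = draw
        else:  # pragma: no cover
            raise AssertionError(category)
        truth_rows.append(
            {
                "site_id": site_id,
                "contig": seq.name,
                "pos": pos,
                "category": category,
                "owner_group": owner,
                "allele_A": allele_a,
                "allele_B": allele_b,
                "verdict": "pass" if category == "diagnostic_clean" else "fail",
                "fail_stage": EXPECTED_FAIL_STAGE[category],
            }
        )

    if config.genotyping_error > 0:
        miscall = (rng.random(calls.shape) < config.genotyping_error) & (
            calls != MISSING
        )
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(miscall, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)

    seq.bases = "".join(bases)
    matrix = GenotypeMatrix(individuals=individuals, sites=sites, calls=calls)
    truth = pd.DataFrame(truth_rows)
    return matrix, popmap, truth


def simulate_dataset(config: SimConfig) -> SimResult:
    """Reference + genotypes + popmap + truth table in one call."""
    reference = make_reference(config)
    matrix, popmap, truth = simulate_genotypes(config, reference)
    return SimResult(reference=reference, matrix=matrix, popmap=popmap, truth=truth)


def expected_fixed_difference_stats() -> dict[str, dict[str, float]]:
    """Population-level Hobs/Hexp/FIS at a fixed-difference site.

    Parental groups are monomorphic (Hexp = 0, FIS = 0 by convention); F1
    hybrids are obligate heterozygotes, so Hobs = 1, the sample allele
    frequency is 1/2, Hexp = 1/2 and FIS = (0.5 - 1)/0.5 = -1.
    """
    return {
        "parental": {"hobs": 0.0, "hexp": 0.0, "fis": 0.0},
        "hybrid": {"hobs": 1.0, "hexp": 0.5, "fis": -1.0},
    }


def expected_shared_stats(
    p_a: float, p_b: float | None = None, fis_parental: float = 0.0
) -> dict[str, dict[str, float]]:
    """Population-level expectations at a shared polymorphic site.

    ``p_a``/``p_b`` are the alt-allele frequencies in the two species. In a
    parental group with frequency p, Hexp = 2p(1-p), Hobs = 2p(1-p)(1-F) and
    FIS = F. In the F1 groups each genotype is one gamete per species, so
    Hobs = p_a(1-p_b) + p_b(1-p_a) while Hexp is computed at the pooled
    frequency (p_a+p_b)/2; the deficit (Hexp - Hobs) = -(p_a-p_b)^2/2 makes
    hybrid FIS <= 0 whenever the species frequencies differ.
    """
    if p_b is None:
        p_b = p_a
    hexp_a = 2 * p_a * (1 - p_a)
    hexp_b = 2 * p_b * (1 - p_b)
    hobs_hyb = p_a * (1 - p_b) + p_b * (1 - p_a)
    p_bar = (p_a + p_b) / 2
    hexp_hyb = 2 * p_bar * (1 - p_bar)
    fis_hyb = (hexp_hyb - hobs_hyb) / hexp_hyb if hexp_hyb > 0 else 0.0
    return {
        "parental_A": {
            "hobs": hexp_a * (1 - fis_parental),
            "hexp": hexp_a,
            "fis": fis_parental if hexp_a > 0 else 0.0,
        },
        "parental_B": {
            "hobs": hexp_b * (1 - fis_parental),
            "hexp": hexp_b,
            "fis": fis_parental if hexp_b > 0 else 0.0,
        },
        "hybrid": {"hobs": hobs_hyb, "hexp": hexp_hyb, "fis": fis_hyb},
    }


def expected_stats(config: SimConfig) -> pd.DataFrame:
    """Closed-form expectations per planted category at representative freqs.

    Shared-site rows are evaluated at the midpoint of ``maf_range`` for both
    species; they describe population-level values, not small-sample ones.
    """
    rows = []
    fixed = expected_fixed_difference_stats()
    for kind in ("parental", "hybrid"):
        rows.append({"category": "diagnostic_clean", "group_kind": kind, **fixed[kind]})
    p_mid = sum(config.maf_range) / 2
    shared = expected_shared_stats(p_mid, p_mid, config.fis_parental)
    rows.append(
        {"category": "shared", "group_kind": "parental", **shared["parental_A"]}
    )
    rows.append({"category": "shared", "group_kind": "hybrid", **shared["hybrid"]})
    priv = expected_shared_stats(config.private_freq, 0.0, config.fis_parental)
    rows.append(
        {"category": "private", "group_kind": "owner", **priv["parental_A"]}
    )
    return pd.DataFrame(rows)
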