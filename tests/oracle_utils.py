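"""Independent brute-force oracles used by the tests.

These are deliberately naive pure-Python tallies, written without reference
to the vectorized implementations they check.
"""

from diagmark.io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, PopMap


def oracle_group_stats(matrix: GenotypeMatrix, popmap: PopMap, group: str, j: int):
    """(n_called, p_ref, hobs, hexp, fis) for one site and group, by direct count."""
    calls = [
        matrix.calls[i, j]
        for i, ind in enumerate(matrix.individuals)
        if popmap.assignments[ind] == group
    ]
    called = [c for c in calls if c != MISSING]
    if not called:
        return 0, None, None, None, None
    n = len(called)
    alt = sum({HOM_REF: 0, HET: 1, HOM_ALT: 2}[c] for c in called)
    p_alt = alt / (2 * n)
    p_ref = 1 - p_alt
    hobs = sum(1 for c in called if c == HET) / n
    hexp = 2 * p_ref * p_alt
    fis = (hexp - hobs) / hexp if hexp > 0 else 0.0
    return n, p_ref, hobs, hexp, fis


def oracle_pooled_maf(matrix: GenotypeMatrix, j: int):
    """Pooled minor allele frequency over all called alleles at site j."""
    alt = ref = 0
    for i in range(matrix.n_individuals):
        c = matrix.calls[i, j]
        if c == MISSING:
            continue
        a = {HOM_REF: 0, HET: 1, HOM_ALT: 2}[c]
        alt += a
        ref += 2 - a
    total = alt + ref
    if total == 0:
        return None
    return min(alt, ref) / total


def oracle_digest_boundaries(bases: str, motif_a: str, off_a: int,
                             motif_b: str, off_b: int):
    """Naive window scan: labelled cut coordinates for a double digest."""
    text = bases.upper()
    cuts = []
    for motif, off, label in ((motif_a, off_a, "ENZ_A"), (motif_b, off_b, "ENZ_B")):
        for s in range(len(text) - len(motif) + 1):
            if text[s : s + len(motif)] == motif:
                c = s + off
                if 0 < c < len(text):
                    cuts.append((c, label))
    return sorted(cuts)


def oracle_fragment_intervals(bases: str, motif_a: str, off_a: int,
                              motif_b: str, off_b: int):
    """(start, end) intervals implied by the naive boundary scan."""
    coords = [0] + [c for c, _ in oracle_digest_boundaries(
        bases, motif_a, off_a, motif_b, off_b)] + [len(bases)]
    return list(zip(coords, coords[1:]))
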