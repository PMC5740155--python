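"""SNP retention rules: biallelic, quality, depth, Hardy-Weinberg.

Retention requires a biallelic SNP with QUAL strictly greater than 10, a
per-site mean depth of at most 100, and a Hardy-Weinberg exact-test P of
at least 0.01 in every population (testing per population rather than
pooled avoids confusing the Wahlund effect of population structure with
genotyping error).  Rules are attributed in the fixed order
biallelic -> qual -> depth -> hwe: a site failing several rules is
counted against the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import MISSING, GenotypeTable

__all__ = ["FilterReport", "hwe_exact_p", "filter_sites"]

RULES = ("biallelic", "qual", "depth", "hwe")


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})

    def as_rows(self) -> list[tuple[str, int]]:
        return [("input", self.n_input)] + [
            (r, self.removed[r]) for r in RULES
        ] + [("retained", self.n_retained)]


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (Levene / Haldane).

    Conditions on the allele counts and sums the probabilities of every
    heterozygote configuration whose conditional probability does not
    exceed that of the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotypes")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)
    # log-probability of h heterozygotes given allele counts
    def logp(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = (max(nA, na) - h) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2.0)
            + math.lgamma(nA + 1)
            + math.lgamma(na + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = [h for h in range(rare % 2, rare + 1, 2)]
    logs = {h: logp(h) for h in hs}
    obs = logs[n_Aa]
    tot = 0.0
    for h in hs:
        if logs[h] <= obs + 1e-12:
            tot += math.exp(logs[h])
    return min(1.0, tot)


def _hwe_fails(site, table: GenotypeTable, alpha: float) -> bool:
    for idx in table.populations.values():
        g = site.genotypes[idx]
        g = g[g != MISSING]
        if len(g) == 0:
            continue
        n_aa = int((g == 2).sum())
        n_Aa = int((g == 1).sum())
        n_AA = int((g == 0).sum())
        if hwe_exact_p(n_AA, n_Aa, n_aa) < alpha:
            return True
    return False


def filter_sites(
    table: GenotypeTable,
    qual_min: float = 10.0,
    depth_max: float = 100.0,
    hwe_alpha: float = 0.01,
) -> tuple[GenotypeTable, FilterReport]:
    """Apply the retention rules; return the filtered table and a report.

    A site is retained iff it is a biallelic SNP AND qual > qual_min
    (strict) AND depth <= depth_max AND HWE exact P >= hwe_alpha in every
    population.
    """
    report = FilterReport(n_input=len(table.sites))
    kept = []
    for s in table.sites:
        if not s.is_biallelic_snp:
            report.removed["biallelic"] += 1
        elif not (s.qual > qual_min):
            report.removed["qual"] += 1
        elif s.depth > depth_max:
            report.removed["depth"] += 1
        elif _hwe_fails(s, table, hwe_alpha):
            report.removed["hwe"] += 1
        else:
            kept.append(s)
    report.n_retained = len(kept)
    return (
        GenotypeTable(sites=kept, samples=table.samples, populations=table.populations),
        report,
    )
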