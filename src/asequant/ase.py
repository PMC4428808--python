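"""SNP-level ASE classification.

A testable SNP (≥ 10 unique reads) is classified ASE when its observed
reference fraction lies outside the expected fraction ± 0.15 *and* a
two-sided binomial test of the reference count against the expected fraction
gives p ≤ 0.05. The expected fraction for a SNP is the median observed
reference fraction of all testable SNPs sharing its ordered genotype
(reference base, alternate base — 12 possible values) within the same
library; this per-genotype baseline absorbs residual, genotype-specific
alignment bias. Requiring both criteria rejects highly expressed SNPs with
slight imbalance and lowly expressed SNPs with large imbalance.

The two-sided p-value uses the minimum-likelihood convention: the sum of
binomial point probabilities over all outcomes no more probable than the
observed count. A tail-doubling alternative is available for sensitivity
analysis.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from asequant.counts import SiteCounts
from asequant.variants import HetSite

DEFAULT_DELTA = 0.15
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DEPTH = 10

OrderedGenotype = tuple[str, str]


@dataclass
class BinMedianTable:
    """Per-library, per-ordered-genotype median reference fractions."""

    medians: dict[str, dict[OrderedGenotype, float]]
    fallback: dict[str, float]

    def get(self, library: str, genotype: OrderedGenotype) -> float:
        if library not in self.fallback:
            raise KeyError(f"no medians computed for library {library!r}")
        by_genotype = self.medians.get(library, {})
        if genotype in by_genotype:
            return by_genotype[genotype]
        return self.fallback[library]


@dataclass
class AseCall:
    site: HetSite
    ref_count: int
    alt_count: int
    other_count: int
    expected: float
    observed: float
    delta: float
    p_value: float
    classification: str  # ASE | not_ASE | untestable
    direction: str  # toward_hapA | toward_hapB | balanced
    library: str = "lib1"
    replicate: str = "rep1"

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def hap_a_count(self) -> int:
        return self.ref_count if self.site.ref_haplotype == "A" else self.alt_count

    @property
    def hap_b_count(self) -> int:
        return self.alt_count if self.site.ref_haplotype == "A" else self.ref_count

    @property
    def is_ase(self) -> bool:
        return self.classification == "ASE"


def binomial_two_sided(k: int, n: int, p: float, method: str = "minlike") -> float:
    """Exact two-sided binomial p-value for k successes in n trials.

    ``method="minlike"`` (default) sums Binomial(n, p) point probabilities
    over every outcome whose probability does not exceed that of ``k``;
    ``method="double"`` doubles the smaller one-sided tail. Both are clipped
    to 1. Results are memoized: genome-scale classification re-tests the
    same (k, n, p) triples constantly.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 < p < 1.0:
        raise ValueError("expected proportion must lie strictly inside (0, 1)")
    return _binomial_two_sided_cached(int(k), int(n), float(p), method)


@functools.lru_cache(maxsize=1_000_000)
def _binomial_two_sided_cached(k: int, n: int, p: float, method: str) -> float:
    if method == "minlike":
        pmf = stats.binom.pmf(np.arange(n + 1), n, p)
        # tiny relative slack guards against last-ulp asymmetry of pmf(k)/pmf(n-k)
        total = float(pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum())
        return min(1.0, total)
    if method == "double":
        lower = float(stats.binom.cdf(k, n, p))
        upper = float(stats.binom.sf(k - 1, n, p))
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown two-sided convention {method!r}")


def compute_bin_medians(
    counts: Sequence[SiteCounts], min_depth: int = DEFAULT_MIN_DEPTH
) -> BinMedianTable:
    """Median observed reference fraction per library and ordered genotype.

    Only testable sites (depth ≥ ``min_depth``) with allele-informative reads
    contribute. Each library also gets a library-wide fallback median for
    ordered genotypes unobserved in that library.
    """
    fractions: dict[str, dict[OrderedGenotype, list[float]]] = {}
    all_fracs: dict[str, list[float]] = {}
    for c in counts:
        if not c.testable(min_depth) or c.allelic_depth == 0:
            continue
        rf = c.reference_fraction
        fractions.setdefault(c.library, {}).setdefault(c.ordered_genotype, []).append(rf)
        all_fracs.setdefault(c.library, []).append(rf)
    if counts and not all_fracs:
        raise ValueError("no testable sites in any library; medians undefined")
    medians = {
        lib: {gt: float(np.median(vals)) for gt, vals in by_gt.items()}
        for lib, by_gt in fractions.items()
    }
    fallback = {lib: float(np.median(vals)) for lib, vals in all_fracs.items()}
    return BinMedianTable(medians=medians, fallback=fallback)


def classify_snp(
    counts: SiteCounts,
    medians: BinMedianTable,
    delta_threshold: float = DEFAULT_DELTA,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
    method: str = "minlike",
) -> AseCall:
    """Classify one SNP as ASE / not_ASE / untestable.

    ASE requires |observed − expected| > ``delta_threshold`` *and* two-sided
    binomial p ≤ ``alpha``. Direction is reported against haplotype (the
    haplotype with the larger read count), keeping genic concordance
    phase-aware.
    """
    m = medians.get(counts.library, counts.ordered_genotype)
    if counts.depth < min_depth or counts.allelic_depth == 0:
        return AseCall(
            site=counts.site,
            ref_count=counts.ref_count,
            alt_count=counts.alt_count,
            other_count=counts.other_count,
            expected=m,
            observed=float("nan"),
            delta=float("nan"),
            p_value=float("nan"),
            classification="untestable",
            direction="balanced",
            library=counts.library,
            replicate=counts.replicate,
        )
    observed = counts.reference_fraction
    delta = abs(observed - m)
    p_value = binomial_two_sided(counts.ref_count, counts.allelic_depth, m, method=method)
    is_ase = delta > delta_threshold and p_value <= alpha
    hap_a, hap_b = counts.hap_a_count, counts.hap_b_count
    if hap_a > hap_b:
        direction = "toward_hapA"
    elif hap_b > hap_a:
        direction = "toward_hapB"
    else:
        direction = "balanced"
    return AseCall(
        site=counts.site,
        ref_count=counts.ref_count,
        alt_count=counts.alt_count,
        other_count=counts.other_count,
        expected=m,
        observed=observed,
        delta=delta,
        p_value=p_value,
        classification="ASE" if is_ase else "not_ASE",
        direction=direction,
        library=counts.library,
        replicate=counts.replicate,
    )


def classify_all(
    counts: Sequence[SiteCounts],
    medians: Optional[BinMedianTable] = None,
    **kwargs,
) -> list[AseCall]:
    """Classify a full count set; medians are computed from it when omitted."""
    if medians is None:
        medians = compute_bin_medians(
            counts, min_depth=kwargs.get("min_depth", DEFAULT_MIN_DEPTH)
        )
    return [classify_snp(c, medians, **kwargs) for c in counts]


def calls_to_frame(calls: Sequence[AseCall]):
    """Tabulate calls with the appended classification columns."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "contig": c.site.contig,
                "pos": c.site.position,
                "ref": c.site.ref,
                "alt": c.site.alt,
                "refHap": c.site.ref_haplotype,
                "refCount": c.ref_count,
                "altCount": c.alt_count,
                "otherCount": c.other_count,
                "depth": c.depth,
                "median": c.expected,
                "refFraction": c.observed,
                "delta": c.delta,
                "pvalue": c.p_value,
                "class": c.classification,
                "direction": c.direction,
                "library": c.library,
                "replicate": c.replicate,
            }
        )
    return pd.DataFrame(rows)


def frame_to_calls(frame) -> list[AseCall]:
    """Rebuild :class:`AseCall` objects from the call TSV schema."""
    out = []
    for row in frame.to_dict("records"):
        site = HetSite(
            contig=str(row["contig"]),
            position=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            ref_haplotype=row["refHap"],
        )
        out.append(
            AseCall(
                site=site,
                ref_count=int(row["refCount"]),
                alt_count=int(row["altCount"]),
                other_count=int(row["otherCount"]),
                expected=float(row["median"]),
                observed=float(row["refFraction"]),
                delta=float(row["delta"]),
                p_value=float(row["pvalue"]),
                classification=row["class"],
                direction=row["direction"],
                library=str(row["library"]),
                replicate=str(row["replicate"]),
            )
        )
    return out


def add_bh_fdr(frame):
    """Optional Benjamini–Hochberg column over testable SNPs."""
    import pandas as pd

    frame = frame.copy()
    mask = frame["class"] != "untestable"
    fdr = pd.Series(float("nan"), index=frame.index)
    if mask.any():
        fdr.loc[mask] = stats.false_discovery_control(
            frame.loc[mask, "pvalue"], method="bh"
        )
    frame["fdr_bh"] = fdr
    return frame
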