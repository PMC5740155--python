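"""Simulation-calibrated outlier scan for selected genomic windows.

Null distributions of Tajima's D, pi and FST are generated by simulating
10 kb windows under the fitted founder model; a window is called a
selection candidate only when all three statistics fall in their
one-tailed 5% extremes (low D, low pi, high FST) with the correct signs
(D < 0 and FST > 0).  Empirical P-values use the add-one rank rule so a
Monte-Carlo P can never be exactly zero.

No multiple-testing correction is applied across windows: the criterion
is per-window P < alpha for each statistic, which is deliberately
liberal per statistic and conservative jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import WindowStats, Window
from .simulate import DemographicModel, simulate_null_windows

__all__ = [
    "NullDistributions",
    "CandidateRegion",
    "calibrate_null",
    "empirical_p",
    "call_outliers",
    "map_to_genes",
]


@dataclass
class NullDistributions:
    """Sorted simulated null values of D, pi (per 10 kb) and FST."""

    d: np.ndarray
    pi: np.ndarray
    fst: np.ndarray
    R: int
    window_size: int
    n_undefined_d: int = 0
    n_undefined_fst: int = 0

    def thresholds(self, alpha: float = 0.05) -> dict[str, float]:
        """One-tailed alpha order-statistic thresholds.

        The lower-tail threshold at alpha with R stored values is the
        floor(alpha*R)-th smallest value; upper tail symmetric.
        """
        def lo(arr):
            k = max(1, int(np.floor(alpha * len(arr))))
            return float(np.sort(arr)[k - 1])

        def hi(arr):
            k = max(1, int(np.floor(alpha * len(arr))))
            return float(np.sort(arr)[len(arr) - k])

        return {"d_low": lo(self.d), "pi_low": lo(self.pi), "fst_high": hi(self.fst)}


def calibrate_null(
    model: DemographicModel,
    n_reps: int = 10_000,
    window: int = 10_000,
    seed: int | None = None,
    n1: int = 16,
    n2: int = 16,
) -> NullDistributions:
    """Simulate ``n_reps`` neutral windows and store their statistics.

    Replicates whose scanned sample has no segregating site (undefined D)
    are excluded from the D array but counted; likewise undefined FST.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sims = simulate_null_windows(model, n_reps, n1=n1, n2=n2, L=window, seed=seed)
    d = sims["tajima_d"]
    fst = sims["fst"]
    return NullDistributions(
        d=np.sort(d[~np.isnan(d)]),
        pi=np.sort(sims["pi_10kb"]),
        fst=np.sort(fst[~np.isnan(fst)]),
        R=n_reps,
        window_size=window,
        n_undefined_d=int(np.isnan(d).sum()),
        n_undefined_fst=int(np.isnan(fst).sum()),
    )


def empirical_p(x: float, null: np.ndarray, tail: str) -> float:
    """Monte-Carlo P with the add-one rule: (1 + #as-or-more-extreme)/(R+1)."""
    null = np.asarray(null)
    if tail == "lower":
        c = int((null <= x).sum())
    elif tail == "upper":
        c = int((null >= x).sum())
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + c) / (len(null) + 1)


@dataclass
class CandidateRegion:
    window: Window
    p_d: float
    p_pi: float
    p_fst: float
    tajima_d: float
    pi_10kb: float
    fst: float
    genes: list[str] = field(default_factory=list)


def call_outliers(
    stats: list[WindowStats],
    null: NullDistributions,
    alpha: float = 0.05,
) -> list[CandidateRegion]:
    """Jointly significant windows: low D, low pi, high FST, all P < alpha.

    Partial trailing windows and windows with undefined D or FST are
    never called.  Sign constraints (D < 0, FST > 0) are enforced on top
    of the empirical P-values.
    """
    out: list[CandidateRegion] = []
    for ws in stats:
        if ws.window.partial or ws.tajima_d is None or ws.fst is None:
            continue
        p_d = empirical_p(ws.tajima_d, null.d, "lower")
        p_pi = empirical_p(ws.pi_10kb, null.pi, "lower")
        p_fst = empirical_p(ws.fst, null.fst, "upper")
        if (
            p_d < alpha
            and p_pi < alpha
            and p_fst < alpha
            and ws.tajima_d < 0
            and ws.fst > 0
        ):
            out.append(
                CandidateRegion(
                    window=ws.window,
                    p_d=p_d,
                    p_pi=p_pi,
                    p_fst=p_fst,
                    tajima_d=ws.tajima_d,
                    pi_10kb=ws.pi_10kb,
                    fst=ws.fst,
                )
            )
    return out


def map_to_genes(
    regions: list[CandidateRegion], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Candidate genes: >= 1 bp overlap between a called window and a gene body.

    ``annotation`` needs columns chrom, start, end (0-based half-open),
    gene_id.  Genes are deduplicated; the most extreme statistic across
    a gene's overlapping called windows is reported (minimum D and pi,
    maximum FST, minimum P-values).
    """
    rows = []
    for _, g in annotation.iterrows():
        hits = [
            r
            for r in regions
            if r.window.chrom == g["chrom"]
            and r.window.start < g["end"]
            and g["start"] < r.window.end
        ]
        if not hits:
            continue
        rows.append(
            {
                "gene_id": g["gene_id"],
                "chrom": g["chrom"],
                "gene_start": int(g["start"]),
                "gene_end": int(g["end"]),
                "n_windows": len(hits),
                "tajima_d": min(r.tajima_d for r in hits),
                "pi_10kb": min(r.pi_10kb for r in hits),
                "fst": max(r.fst for r in hits),
                "p_d": min(r.p_d for r in hits),
                "p_pi": min(r.p_pi for r in hits),
                "p_fst": min(r.p_fst for r in hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "gene_start", "gene_end", "n_windows",
            "tajima_d", "pi_10kb", "fst", "p_d", "p_pi", "p_fst",
        ],
    )
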