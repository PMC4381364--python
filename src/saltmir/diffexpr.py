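"""Two-library differential expression of miRNA counts.

Counts are normalized to transcripts per million of clean reads (TPM); a TPM
of zero is replaced by 0.01 so that fold changes stay finite.  Significance
for one sequence class across two un-replicated libraries uses the exact
count-comparison test: conditional on the combined count n = x + y, the
treated-library count is Binomial(n, N2/(N1+N2)) under the null of equal
relative abundance, which is the Audic-Claverie statistic evaluated with a
fixed combined total.  The two-sided p-value doubles the smaller tail, capped
at 1.  A miRNA is called up (down) when log2(TPM ratio) exceeds +0.5 (falls
below -0.5) with p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

FC_CUT = 0.5
P_CUT = 0.05
TPM_FLOOR = 0.01


def normalize(count: int, library_total: int) -> float:
    """TPM = count / total clean reads x 1e6; zero maps to the 0.01 floor."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    tpm = count / library_total * 1_000_000
    return TPM_FLOOR if tpm == 0 else tpm


def count_pvalue(x: int, y: int, n1: int, n2: int, method: str = "binomial") -> float:
    """Two-sided exact p-value for count x in library 1 vs count y in library 2.

    method='binomial' (default): exact conditional test, Y | x+y ~
    Binomial(x+y, N2/(N1+N2)); the smaller of P(Y<=y) and P(Y>=y) is doubled.
    method='ac': the Audic-Claverie negative-binomial series
    P(k|x) = (N2/N1)^k (x+k)! / (x! k! (1+N2/N1)^(x+k+1)), tails over k.
    Both are symmetric under (x,y,N1,N2) <-> (y,x,N2,N1).
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if method == "binomial":
        n = x + y
        if n == 0:
            return 1.0
        p2 = n2 / (n1 + n2)
        lower = stats.binom.cdf(y, n, p2)
        upper = stats.binom.sf(y - 1, n, p2)
    elif method == "ac":
        # Y | x ~ NegativeBinomial(x+1, N1/(N1+N2)) in scipy's (n, p) form.
        p1 = n1 / (n1 + n2)
        lower = stats.nbinom.cdf(y, x + 1, p1)
        upper = stats.nbinom.sf(y - 1, x + 1, p1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, 2.0 * min(float(lower), float(upper)))


@dataclass
class ExpressionRecord:
    mirna: str
    x: int
    y: int
    n1: int
    n2: int
    tpm_ck: float = 0.0
    tpm_na: float = 0.0
    log2fc: float = 0.0
    pvalue: float = 1.0
    call: str = "unchanged"


def build_records(
    counts: Mapping[str, tuple[int, int]],
    n1: int,
    n2: int,
    method: str = "binomial",
) -> list[ExpressionRecord]:
    """Normalize, test and fold-change every miRNA.

    ``counts`` maps miRNA name -> (CK count, Na200 count); ``n1``/``n2`` are
    the clean-read totals of the CK and Na200 libraries.
    """
    records = []
    for name in counts:
        x, y = counts[name]
        rec = ExpressionRecord(name, x, y, n1, n2)
        rec.tpm_ck = normalize(x, n1)
        rec.tpm_na = normalize(y, n2)
        rec.log2fc = math.log2(rec.tpm_na / rec.tpm_ck)
        rec.pvalue = count_pvalue(x, y, n1, n2, method=method)
        records.append(rec)
    return records


def call_regulation(
    records: Iterable[ExpressionRecord],
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    bh_correct: bool = False,
) -> tuple[list[ExpressionRecord], dict[str, int]]:
    """Apply the threshold rule and sort by |log2fc| descending.

    Strict inequalities: log2fc must exceed +fc_cut (or fall below -fc_cut)
    AND p < p_cut.  ``bh_correct`` applies Benjamini-Hochberg to the p-values
    before thresholding (off by default; no multiple-testing correction is
    applied in the reference workflow).
    """
    records = list(records)
    pvals = [r.pvalue for r in records]
    if bh_correct and records:
        pvals = list(stats.false_discovery_control(pvals, method="bh"))
    n_up = n_down = 0
    for rec, p in zip(records, pvals):
        if rec.log2fc > fc_cut and p < p_cut:
            rec.call = "up"
            n_up += 1
        elif rec.log2fc < -fc_cut and p < p_cut:
            rec.call = "down"
            n_down += 1
        else:
            rec.call = "unchanged"
    records.sort(key=lambda r: (-abs(r.log2fc), r.mirna))
    return records, {"up": n_up, "down": n_down}


def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna,
            "count_ck": r.x,
            "count_na": r.y,
            "tpm_ck": r.tpm_ck,
            "tpm_na": r.tpm_na,
            "log2fc": r.log2fc,
            "pvalue": r.pvalue,
            "call": r.call,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "count_ck", "count_na", "tpm_ck", "tpm_na", "log2fc", "pvalue", "call"],
    )
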