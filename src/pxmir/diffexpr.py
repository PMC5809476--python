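"""Count-based differential expression between two sequencing libraries.

Implements the Audic–Claverie exact test for comparing a tag's raw count in
two libraries of different depths, together with transcripts-per-million
normalization, the low-expression filter, Bonferroni correction and
up/down/ns classification used for volcano reporting.

The test conditions on the count ``x`` observed in the first library and asks
how surprising the count ``y`` in the second library is under the null
hypothesis of equal underlying expression.  With library totals ``N1`` and
``N2`` and ``r = N2/N1`` the null probability of observing ``y`` given ``x``
is::

    p(y|x) = r**y * (x+y)! / (x! * y!) * (1 + r)**-(x+y+1)

which is a negative-binomial tail-friendly posterior predictive; it sums to
one over y for any fixed x.  All computations are done in log space via
``lgamma`` so counts up to ~1e7 are safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTestResult",
    "normalize_tpm",
    "filter_low_expression",
    "ac_point_probability",
    "ac_test",
    "classify_de",
]

#: TPM value substituted for exact zeros before ratios are formed.
TPM_ZERO_SUB = 0.01


@dataclass
class ACTestResult:
    """Exact-test outcome for one miRNA in one treatment-vs-control pair.

    ``C`` is the lower-tail probability ``sum_{y'<=y} p(y'|x)``, ``D`` the
    upper tail ``sum_{y'>=y} p(y'|x)``; they overlap in the point mass so
    ``C + D = 1 + p(y|x)``.
    """

    mirna: str
    x: int
    y: int
    N1: float
    N2: float
    tpm_control: float
    tpm_treatment: float
    log2fc: float
    C: float
    D: float
    p_value: float
    p_corrected: float = math.nan
    regulation: str = "ns"


def normalize_tpm(raw_counts: pd.DataFrame, clean_totals: dict[str, int] | pd.Series,
                  *, zero_sub: float = TPM_ZERO_SUB) -> pd.DataFrame:
    """Normalize a miRNA x library count matrix to transcripts per million.

    tpm = count / library clean-read total * 1e6.  Exact zeros are replaced
    by ``zero_sub`` (default 0.01) so downstream log-ratios stay finite.

    Parameters
    ----------
    raw_counts : DataFrame
        Rows indexed by miRNA name, one column per library.
    clean_totals : mapping
        Library label -> total clean reads (must be positive).
    """
    totals = pd.Series(clean_totals, dtype=float)
    missing = set(raw_counts.columns) - set(totals.index)
    if missing:
        raise ValueError(f"no clean-read total for libraries: {sorted(missing)}")
    if (totals <= 0).any():
        raise ValueError("clean totals must be positive")
    if (raw_counts.to_numpy() < 0).any():
        raise ValueError("negative raw counts")
    tpm = raw_counts.astype(float).div(totals[raw_counts.columns], axis=1) * 1e6
    return tpm.mask(tpm == 0.0, zero_sub)


def filter_low_expression(tpm: pd.DataFrame, *, min_tpm: float = 1.0) -> pd.DataFrame:
    """Drop miRNAs whose TPM is below ``min_tpm`` in every library."""
    return tpm.loc[tpm.max(axis=1) >= min_tpm]


def _log_point_prob(y: int, x: int, log_r: float) -> float:
    # log p(y|x) = y*log r + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
    #              - (x+y+1)*log(1+r)
    return (y * log_r
            + math.lgamma(x + y + 1) - math.lgamma(x + 1) - math.lgamma(y + 1)
            - (x + y + 1) * math.log1p(math.exp(log_r)))


def ac_point_probability(y: int, x: int, N1: float, N2: float) -> float:
    """Null probability p(y|x) of treatment count y given control count x.

    ``N1``/``N2`` are the control/treatment library totals; only their ratio
    enters.  Computed in log space so it is safe for counts up to ~1e7.
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    log_r = math.log(N2) - math.log(N1)
    return math.exp(_log_point_prob(int(y), int(x), log_r))


def ac_test(x: int, y: int, N1: float, N2: float) -> tuple[float, float, float]:
    """Two-sided exact test; returns (C, D, p_value).

    C = P(Y <= y | x), D = P(Y >= y | x); the observed point mass belongs to
    both tails.  The two-sided p-value doubles the smaller tail, capped at 1.
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    log_r = math.log(N2) - math.log(N1)
    # accumulate the lower tail by direct summation in log space; the number
    # of terms is y+1 which is fine up to ~1e7 but we sum the shorter tail
    # when y is enormous relative to the mean.
    ys = np.arange(0, y + 1)
    with np.errstate(divide="ignore"):
        logs = (ys * log_r
                + _lgamma_vec(x + ys + 1) - math.lgamma(x + 1) - _lgamma_vec(ys + 1)
                - (x + ys + 1) * math.log1p(math.exp(log_r)))
    m = logs.max()
    C = float(np.exp(m) * np.exp(logs - m).sum())
    C = min(C, 1.0)
    point = math.exp(logs[-1])
    D = min(1.0, 1.0 - C + point)
    p = min(1.0, 2.0 * min(C, D))
    return C, D, p


def _lgamma_vec(a: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(a)


def classify_de(results: list[ACTestResult], m: int, *, alpha: float = 0.05,
                fc_threshold: float = 1.0) -> pd.DataFrame:
    """Bonferroni-correct and call regulation; returns the volcano table.

    A miRNA is ``up`` when corrected p < alpha and log2fc >= fc_threshold,
    ``down`` when corrected p < alpha and log2fc <= -fc_threshold, else
    ``ns``.  ``m`` is the number of tests in the comparison.
    """
    if m <= 0:
        raise ValueError("number of tests m must be positive")
    rows = []
    for r in results:
        r.p_corrected = min(1.0, m * r.p_value)
        if r.p_corrected < alpha and r.log2fc >= fc_threshold:
            r.regulation = "up"
        elif r.p_corrected < alpha and r.log2fc <= -fc_threshold:
            r.regulation = "down"
        else:
            r.regulation = "ns"
        rows.append({
            "mirna": r.mirna,
            "log2fc": r.log2fc,
            "neg_log10_p_corrected": -math.log10(max(r.p_corrected, 1e-300)),
            "call": r.regulation,
        })
    return pd.DataFrame(rows, columns=["mirna", "log2fc", "neg_log10_p_corrected", "call"])


def test_all(counts: pd.DataFrame, clean_totals: dict[str, int], control: str,
             treatments: list[str] | None = None, *, alpha: float = 0.05,
             fc_threshold: float = 1.0, min_tpm: float = 1.0,
             ) -> dict[str, list[ACTestResult]]:
    """Run the full DE stage: TPM filter, exact test and classification.

    Returns a mapping treatment label -> list of ACTestResult (classified).
    """
    if treatments is None:
        treatments = [c for c in counts.columns if c != control]
    tpm = normalize_tpm(counts, clean_totals)
    tpm = filter_low_expression(tpm, min_tpm=min_tpm)
    kept = counts.loc[tpm.index]
    out: dict[str, list[ACTestResult]] = {}
    for trt in treatments:
        res = []
        N1, N2 = float(clean_totals[control]), float(clean_totals[trt])
        for mirna, row in kept.iterrows():
            x, y = int(row[control]), int(row[trt])
            C, D, p = ac_test(x, y, N1, N2)
            t_c, t_t = tpm.at[mirna, control], tpm.at[mirna, trt]
            res.append(ACTestResult(
                mirna=mirna, x=x, y=y, N1=N1, N2=N2,
                tpm_control=t_c, tpm_treatment=t_t,
                log2fc=math.log2(t_t / t_c), C=C, D=D, p_value=p))
        classify_de(res, m=len(res), alpha=alpha, fc_threshold=fc_threshold)
        out[trt] = res
    return out
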