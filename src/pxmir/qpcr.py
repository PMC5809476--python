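"""Relative quantification from qPCR Ct tables by the 2^-ddCt method.

Each replicate's target Ct is normalized against the reference assay
(U6-style small RNA) to give dCt; subtracting the calibrator group's mean
dCt gives ddCt and the relative quantity RQ = 2^-ddCt.  Group comparisons
use one-way ANOVA followed by Tukey's HSD, summarized as compact letter
displays at alpha = 0.05 (lowercase) and 0.01 (uppercase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrRecord", "delta_delta_ct", "group_summary", "group_stats"]


@dataclass
class QpcrRecord:
    target: str
    group: str
    replicate: int
    ct_target: float
    ct_reference: float
    dct: float
    ddct: float
    rq: float


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"target", "group", "replicate", "ct_target", "ct_reference"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def delta_delta_ct(ct: pd.DataFrame, calibrator: str) -> list[QpcrRecord]:
    """Per-replicate ddCt relative to the calibrator group's mean dCt."""
    if calibrator not in set(ct["group"]):
        raise ValueError(f"calibrator group {calibrator!r} missing from table")
    out: list[QpcrRecord] = []
    for target, sub in ct.groupby("target", sort=True):
        dct = sub["ct_target"] - sub["ct_reference"]
        cal_mean = dct[sub["group"] == calibrator].mean()
        if np.isnan(cal_mean):
            raise ValueError(f"no calibrator replicates for target {target!r}")
        for (_, row), d in zip(sub.iterrows(), dct):
            ddct = d - cal_mean
            out.append(QpcrRecord(target, row["group"], int(row["replicate"]),
                                  float(row["ct_target"]),
                                  float(row["ct_reference"]),
                                  float(d), float(ddct),
                                  float(2.0 ** -ddct)))
    return out


def group_summary(records: list[QpcrRecord]) -> pd.DataFrame:
    """Mean and SEM of RQ per (target, group)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    g = df.groupby(["target", "group"])["rq"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "rq_mean", "sem": "rq_sem",
                               "count": "n"})


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups sharing a letter are
    not significantly different."""
    letters: list[set[str]] = []   # each letter = set of groups
    for g in groups:
        placed = False
        for letter in letters:
            if all(frozenset((g, h)) in not_different for h in letter):
                letter.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb letters fully contained in another
    keep = []
    for i, a in enumerate(letters):
        if not any(i != j and a < b for j, b in enumerate(letters)):
            keep.append(a)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for sym, letter in zip(alphabet, keep):
        for g in sorted(letter):
            out[g] += sym
    return out


def group_stats(records: list[QpcrRecord]) -> pd.DataFrame:
    """ANOVA + Tukey HSD per target; compact letters at 0.05 and 0.01.

    Letters are lowercase for alpha = 0.05 and uppercase for alpha = 0.01;
    groups sharing a letter do not differ at that level.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for target, sub in df.groupby("target", sort=True):
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            raise ValueError(f"target {target!r}: need at least 2 groups")
        samples = [sub.loc[sub["group"] == g, "rq"].to_numpy() for g in groups]
        if any(len(s) < 3 for s in samples):
            raise ValueError(f"target {target!r}: need >= 3 replicates per group")
        if all(np.allclose(s, s[0]) for s in samples) and \
                len({s[0] for s in samples}) == 1:
            # all values identical everywhere: no variance to test against
            raise ValueError(f"target {target!r}: degenerate zero variance")
        f_stat, anova_p = stats.f_oneway(*samples)
        letters = {}
        for alpha, case in ((0.05, str.lower), (0.01, str.upper)):
            tk = pairwise_tukeyhsd(sub["rq"].to_numpy(),
                                   sub["group"].to_numpy(), alpha=alpha)
            nd = set()
            res = tk.summary().data[1:]
            for row in res:
                g1, g2, reject = str(row[0]), str(row[1]), bool(row[6])
                if not reject:
                    nd.add(frozenset((g1, g2)))
            cl = _compact_letters(groups, nd)
            letters[alpha] = {g: case(s) for g, s in cl.items()}
        for g in groups:
            rq = sub.loc[sub["group"] == g, "rq"]
            rows.append({
                "target": target, "group": g,
                "rq_mean": rq.mean(), "rq_sem": rq.sem(),
                "anova_p": float(anova_p),
                "letters_05": letters[0.05][g],
                "letters_01": letters[0.01][g],
            })
    return pd.DataFrame(rows)
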