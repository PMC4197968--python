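"""Intron architecture groups, rank-sum tests, and transcript-level size bins.

Groups follow the architecture of the intron within its transcript: ordinal
position, size of the intron itself and of its immediate neighbors
(large = > 2 kb), presence of a huge (> 10 kb) intron anywhere in the
transcript, and polypyrimidine-tract quality.  Labels are not mutually
exclusive.  Each group's retention fold changes are compared against all
analyzed introns outside the group with the two-sample Wilcoxon rank-sum
(Mann-Whitney U) test: exact enumeration over all member/non-member
assignments when the pooled size is small, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intronret.annotation_model import IntronRecord

LABEL_FIRST = "FIRST"
LABEL_FIRST_BEFORE_LARGE_SECOND = "FIRST_BEFORE_LARGE_SECOND"
LABEL_INTERNAL_AFTER_LARGE = "INTERNAL_AFTER_LARGE"
LABEL_INTERNAL_BEFORE_LARGE = "INTERNAL_BEFORE_LARGE"
LABEL_LARGE = "LARGE"
LABEL_HUGE_TRANSCRIPT = "IN_TRANSCRIPT_WITH_HUGE_INTRON"
LABEL_POOR_PY = "POOR_PY"

ALL_LABELS = [
    LABEL_FIRST,
    LABEL_FIRST_BEFORE_LARGE_SECOND,
    LABEL_INTERNAL_AFTER_LARGE,
    LABEL_INTERNAL_BEFORE_LARGE,
    LABEL_LARGE,
    LABEL_HUGE_TRANSCRIPT,
    LABEL_POOR_PY,
]

BIN_LABELS = ["(0,0.5]kb", "(0.5,2]kb", "(2,10]kb", "(10,inf)kb"]
_BIN_EDGES_NT = [0, 500, 2000, 10000]


@dataclass
class GroupScheme:
    """Size thresholds of the architecture groups (nucleotides)."""

    large_intron_min: int = 2000
    huge_intron_min: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.large_intron_min < self.huge_intron_min:
            raise ValueError("need 0 < large_intron_min < huge_intron_min")


@dataclass
class GroupTestResult:
    label: str
    n_members: int
    n_comparison: int
    median_fold: float
    p_value: float
    status: str = "ok"


def classify_intron_groups(
    intron: IntronRecord,
    scheme: GroupScheme | None = None,
    py_good: bool | None = None,
    transcript_max_intron: int | None = None,
) -> set[str]:
    """Architecture labels of one intron (labels are not exclusive).

    ``py_good`` and ``transcript_max_intron`` (largest intron of the parent
    transcript) supply context the record itself does not carry; the
    corresponding labels are omitted when the context is missing.
    """
    scheme = scheme or GroupScheme()
    labels: set[str] = set()
    large = scheme.large_intron_min
    if intron.is_first:
        labels.add(LABEL_FIRST)
        down = intron.downstream_intron_length
        if down is not None and down > large:
            labels.add(LABEL_FIRST_BEFORE_LARGE_SECOND)
    if not intron.is_first and not intron.is_last:
        up = intron.upstream_intron_length
        down = intron.downstream_intron_length
        if up is not None and up > large:
            labels.add(LABEL_INTERNAL_AFTER_LARGE)
        if down is not None and down > large:
            labels.add(LABEL_INTERNAL_BEFORE_LARGE)
    if intron.length > large:
        labels.add(LABEL_LARGE)
    if transcript_max_intron is not None and transcript_max_intron > scheme.huge_intron_min:
        labels.add(LABEL_HUGE_TRANSCRIPT)
    if py_good is False:
        labels.add(LABEL_POOR_PY)
    return labels


def classify_table(
    introns: Sequence[IntronRecord],
    py_status: Mapping[str, bool] | None = None,
    scheme: GroupScheme | None = None,
) -> pd.DataFrame:
    """Boolean label matrix (intron_id x label) for a set of introns.

    ``py_status`` maps intron_id to pY-tract presence; when omitted the
    POOR_PY column is all False.
    """
    scheme = scheme or GroupScheme()
    max_by_transcript: dict[str, int] = {}
    for rec in introns:
        cur = max_by_transcript.get(rec.transcript_id, 0)
        max_by_transcript[rec.transcript_id] = max(cur, rec.length)
    rows = []
    for rec in introns:
        labels = classify_intron_groups(
            rec,
            scheme,
            py_good=None if py_status is None else py_status.get(rec.intron_id),
            transcript_max_intron=max_by_transcript[rec.transcript_id],
        )
        rows.append({"intron_id": rec.intron_id, **{lb: lb in labels for lb in ALL_LABELS}})
    frame = pd.DataFrame(rows, columns=["intron_id"] + ALL_LABELS)
    return frame.set_index("intron_id")


# ---------------------------------------------------------------------------
# rank-sum testing


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x versus y with midrank ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def exact_ranksum_p(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Exact rank-sum p-value by full enumeration of member assignments.

    Every choice of len(x) members out of the pooled values is enumerated
    and the U statistic compared with the observed one.  Ties are handled by
    midranks.  Two-sided p is 2 * min(P(U <= u), P(U >= u)), capped at 1;
    identical pooled values therefore give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(pooled)
    u_obs = _rank_sum_u(x, y)
    us = []
    idx = np.arange(m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(m, dtype=bool)
        mask[list(comb)] = True
        us.append(_rank_sum_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def group_retention_test(
    folds: pd.Series,
    member_ids: Iterable[str],
    label: str = "",
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> GroupTestResult:
    """Rank-sum test of a group's fold changes against all other introns.

    ``folds`` is indexed by intron_id over the analyzed set; ``member_ids``
    selects the group.  Pooled sizes up to ``exact_max_n`` use exact
    enumeration, larger ones the normal approximation with tie correction.
    """
    member_ids = set(member_ids)
    members = folds.loc[folds.index.isin(member_ids)].to_numpy(dtype=float)
    others = folds.loc[~folds.index.isin(member_ids)].to_numpy(dtype=float)
    if len(members) == 0:
        return GroupTestResult(label, 0, len(others), float("nan"), float("nan"),
                               status="empty group")
    if len(others) == 0:
        return GroupTestResult(label, len(members), 0, float(np.median(members)),
                               float("nan"), status="empty comparison set")
    median = float(np.median(members))
    if len(members) + len(others) <= exact_max_n:
        p = exact_ranksum_p(members, others, alternative)
    elif np.ptp(np.concatenate([members, others])) == 0:
        p = 1.0  # all values identical: no evidence under any convention
    else:
        _, p = stats.mannwhitneyu(
            members, others, alternative=alternative, method="asymptotic"
        )
        p = float(p)
    return GroupTestResult(label, len(members), len(others), median, p)


def run_group_tests(
    folds: pd.Series,
    labels: pd.DataFrame,
    alternative: str = "two-sided",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One rank-sum test per architecture label; returns a tidy frame.

    ``labels`` is the boolean matrix from :func:`classify_table` restricted
    to (or at least covering) the introns in ``folds``.  Benjamini-Hochberg
    adjustment across labels is available but off by default: raw p-values
    are the primary output.
    """
    results = []
    for lb in labels.columns:
        member_ids = labels.index[labels[lb]]
        res = group_retention_test(folds, member_ids, label=lb, alternative=alternative)
        results.append(res)
    frame = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "n_members": [r.n_members for r in results],
            "n_comparison": [r.n_comparison for r in results],
            "median_fold": [r.median_fold for r in results],
            "p_value": [r.p_value for r in results],
            "status": [r.status for r in results],
        }
    )
    if bh_adjust:
        ok = frame["status"] == "ok"
        p = frame.loc[ok, "p_value"].to_numpy()
        if len(p):
            frame.loc[ok, "p_adj"] = _benjamini_hochberg(p)
    return frame


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# transcript-level largest-intron bins


def transcript_intron_size_bins(max_intron_lengths: pd.Series) -> pd.Series:
    """Assign each transcript to one of four bins by its largest intron.

    Boundaries in kb: (0, 0.5], (0.5, 2], (2, 10], (10, inf) — right edges
    closed, so a largest intron of exactly 2,000 nt falls in the second bin.
    Transcripts without introns (length <= 0 or NaN) are excluded.
    """
    lens = max_intron_lengths.dropna()
    lens = lens[lens > 0]
    idx = np.searchsorted(_BIN_EDGES_NT, lens.to_numpy(), side="left") - 1
    idx = np.clip(idx, 0, len(BIN_LABELS) - 1)
    return pd.Series([BIN_LABELS[i] for i in idx], index=lens.index, name="size_bin")


def transcript_level_test(
    transcript_folds: pd.Series,
    bins: pd.Series,
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-bin median transcript-level fold change and rank-sum p versus the rest."""
    common = transcript_folds.index.intersection(bins.index)
    folds = transcript_folds.loc[common]
    bins = bins.loc[common]
    results = []
    for lb in BIN_LABELS:
        member_ids = bins.index[bins == lb]
        res = group_retention_test(
            folds, member_ids, label=lb, alternative=alternative, exact_max_n=exact_max_n
        )
        results.append(res)
    return pd.DataFrame(
        {
            "bin": [r.label for r in results],
            "n_members": [r.n_members for r in results],
            "n_comparison": [r.n_comparison for r in results],
            "median_fold": [r.median_fold for r in results],
            "p_value": [r.p_value for r in results],
            "status": [r.status for r in results],
        }
    )


def plot_group_folds(
    folds: pd.Series,
    labels: pd.DataFrame,
    path: str,
    title: str = "Retention fold change by intron group",
) -> None:
    """Box plot of fold changes per architecture group (log2 scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data, names = [], []
    common = folds.index.intersection(labels.index)
    data.append(np.log2(folds.loc[common].to_numpy()))
    names.append("all")
    for lb in labels.columns:
        ids = labels.index[labels[lb]].intersection(folds.index)
        if len(ids):
            data.append(np.log2(folds.loc[ids].to_numpy()))
            names.append(lb)
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot(data, tick_labels=names, whis=1.5, showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("log2 retention fold change (kd / control)")
    ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
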