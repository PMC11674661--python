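"""Statistical comparison machinery.

Two conditions (e.g. raw vs artifact-rejected) are compared at two
levels.  Across subjects, paired accuracies are tested with the
two-sided Wilcoxon signed-rank test.  Within a subject, the ~15 CV
accuracies per condition are compared with a two-sample test gated on
normality: Shapiro–Wilk on both samples at alpha = 0.05, then Welch's
t-test if both pass, Mann–Whitney U otherwise.  Each such comparison
contributes a score of -1 (significant decline), 0 (no significant
difference) or +1 (significant increase); summing the scores over
networks and runs gives the per-subject cumulative score (bounds
+-networks x runs: +-20 for 5 networks x 4 runs, +-8 for 2 x 4), and
subjects are ranked by it.  No multiple-testing correction is applied
across subjects, mirroring the study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


def paired_wilcoxon(acc_a, acc_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-subject accuracies.

    Zero differences are dropped (the classic Wilcoxon convention); if
    every difference is zero the samples are indistinguishable and p = 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.pvalue)


def subject_significance(dist_a, dist_b, alpha: float = ALPHA) -> int:
    """Score one (subject, network, run) comparison: -1, 0 or +1.

    Positive means ``dist_b`` is significantly larger than ``dist_a``.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per side")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0
    if a.std() == 0 and b.std() == 0:
        # two distinct constants: direction is unambiguous
        return int(np.sign(b.mean() - a.mean()))
    normal = True
    for s in (a, b):
        if s.std() == 0:
            normal = False
            break
        if stats.shapiro(s).pvalue < ALPHA:
            normal = False
            break
    if normal:
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    else:
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    if p < alpha:
        return int(np.sign(b.mean() - a.mean()))
    return 0


@dataclass
class SubjectScore:
    subject: int | str
    scores: pd.DataFrame      # networks x runs of {-1, 0, +1}
    cumulative: int

    def __post_init__(self):
        vals = self.scores.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("scores must be -1, 0 or +1")
        if int(vals.sum()) != self.cumulative:
            raise ValueError("cumulative must equal the sum of the scores")

    @property
    def bound(self) -> int:
        return int(self.scores.size)


def cumulative_score(subject, scores: pd.DataFrame) -> SubjectScore:
    """Sum a complete networks x runs score grid into a SubjectScore."""
    if scores.isna().any().any():
        raise ValueError("score grid has missing cells")
    return SubjectScore(subject=subject, scores=scores,
                        cumulative=int(scores.to_numpy().sum()))


def score_subjects(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   alpha: float = ALPHA) -> list[SubjectScore]:
    """Score every subject from two ResultTables (same subjects/networks).

    One "run" is one repetition of the k-fold CV: the fold accuracies of
    that repetition form the sample entering the significance test.
    """
    scores = []
    subjects = sorted(set(table_a["subject"]))
    for subj in subjects:
        ta = table_a[table_a["subject"] == subj]
        tb = table_b[table_b["subject"] == subj]
        networks = sorted(set(ta["network"]))
        runs = sorted(set(ta["repeat"]))
        grid = pd.DataFrame(index=networks, columns=runs, dtype=float)
        for net in networks:
            for run in runs:
                da = ta[(ta["network"] == net) & (ta["repeat"] == run)]["accuracy"]
                db = tb[(tb["network"] == net) & (tb["repeat"] == run)]["accuracy"]
                grid.loc[net, run] = subject_significance(da, db, alpha)
        scores.append(cumulative_score(subj, grid.astype(int)))
    return scores


def rank_subjects(scores: list[SubjectScore]) -> pd.DataFrame:
    """Stable descending sort by cumulative score; ties keep input order."""
    rows = [{"subject": s.subject, "cumulative": s.cumulative,
             "bound": s.bound} for s in scores]
    df = pd.DataFrame(rows)
    df = df.sort_values("cumulative", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def score_heatmap(scores: list[SubjectScore], path=None):
    """Render the ranked subject x (network, run) score grid as a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = rank_subjects(scores)["subject"].tolist()
    by_subject = {s.subject: s for s in scores}
    mat = np.stack([by_subject[s].scores.to_numpy().ravel() for s in order])
    fig, ax = plt.subplots(figsize=(max(6, mat.shape[1] * 0.5),
                                    max(4, mat.shape[0] * 0.25)))
    ax.imshow(mat, cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
    ax.set_yticks(range(len(order)), labels=[str(s) for s in order])
    ax.set_xlabel("network x run")
    ax.set_ylabel("subject (ranked by cumulative score)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
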