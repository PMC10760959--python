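"""Predicted antigen presentation in a cohort and survival stratification.

An antigen is *presented* in a cohort sample only when (a) its
MAP-coding transcript is highly expressed there — above 2 rphm and
above the antigen's nonnull median, i.e. the median over samples with
any expression — and (b) the patient carries an HLA allotype predicted
to present the peptide (eluted-ligand rank below 2%). Samples are split
at the cohort median of their presented-antigen counts (high: strictly
above; low: at or below) and the two groups are compared with a
two-group log-rank test.

The expression-only control repeats the split counting antigens that
are expressed but lack a presenting HLA allele; contrasting the two
splits isolates the HLA-restricted component of any survival signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import BindingPredictor, min_rank

__all__ = [
    "PresentationMatrix",
    "presentation_matrix",
    "median_split",
    "logrank_test",
    "expression_only_control",
    "survival_analysis",
]

EXPR_CUTOFF = 2.0  # rphm
RANK_CUTOFF = 2.0  # percentile

ABSENT, EXPRESSED_NOT_PRESENTED, PRESENTED = 0, 1, 2


@dataclass
class PresentationMatrix:
    """Antigens x samples presentation states with per-antigen nonnull medians."""

    antigen_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray  # int8, codes ABSENT / EXPRESSED_NOT_PRESENTED / PRESENTED
    nonnull_median: dict[str, float] = field(default_factory=dict)

    def presented_counts(self) -> dict[str, int]:
        counts = (self.states == PRESENTED).sum(axis=0)
        return dict(zip(self.sample_ids, counts.tolist()))

    def expressed_counts(self) -> dict[str, int]:
        """Antigens expressed regardless of HLA (presented or not)."""
        counts = (self.states >= EXPRESSED_NOT_PRESENTED).sum(axis=0)
        return dict(zip(self.sample_ids, counts.tolist()))

    def expressed_not_presented_counts(self) -> dict[str, int]:
        counts = (self.states == EXPRESSED_NOT_PRESENTED).sum(axis=0)
        return dict(zip(self.sample_ids, counts.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        labels = np.array(["absent", "expressed-not-presented", "presented"])
        df = pd.DataFrame(
            labels[self.states], index=self.antigen_ids, columns=self.sample_ids
        )
        df.index.name = "antigen_id"
        df.to_csv(path, sep="\t")


def presentation_matrix(
    antigens: Sequence,
    cohort,
    predictor: BindingPredictor,
    expr_cutoff: float = EXPR_CUTOFF,
    rank_cutoff: float = RANK_CUTOFF,
) -> PresentationMatrix:
    """Evaluate the presentation rule for every (antigen, sample) pair.

    ``antigens`` need ``id`` and ``peptide`` attributes; ``cohort``
    provides per-sample HLA alleles and antigen-id -> rphm expression.
    An antigen with zero expression in every sample has an undefined
    nonnull median and is never expressed (a warning is emitted).
    """
    samples = cohort.samples
    if not samples:
        raise ValueError("empty cohort")
    antigen_ids = [a.id for a in antigens]
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        # one biopsy per patient: duplicated ids would double-count a patient
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicated patient ids in cohort: {dupes}")
    states = np.zeros((len(antigens), len(samples)), dtype=np.int8)
    medians: dict[str, float] = {}

    # binder lookup per (antigen, sample): best rank over the sample's alleles
    binder = np.zeros((len(antigens), len(samples)), dtype=bool)
    for i, a in enumerate(antigens):
        for j, s in enumerate(samples):
            rank, _ = min_rank(predictor, a.peptide, s.hla_alleles)
            binder[i, j] = rank < rank_cutoff

    for i, a in enumerate(antigens):
        values = np.array([s.expression.get(a.id, 0.0) for s in samples])
        nonnull = values[values > 0]
        if nonnull.size == 0:
            warnings.warn(f"antigen {a.id!r} has zero expression in all cohort samples")
            continue
        med = float(np.median(nonnull))
        medians[a.id] = med
        expressed = (values > expr_cutoff) & (values > med)
        states[i, expressed & binder[i]] = PRESENTED
        states[i, expressed & ~binder[i]] = EXPRESSED_NOT_PRESENTED
    return PresentationMatrix(
        antigen_ids=antigen_ids,
        sample_ids=sample_ids,
        states=states,
        nonnull_median=medians,
    )


def median_split(counts: Mapping[str, int | float]) -> tuple[set[str], set[str]]:
    """(high, low) groups: high is strictly above the median, low at or below."""
    if len(counts) < 2:
        raise ValueError("median split needs at least 2 samples")
    values = np.array(list(counts.values()), dtype=float)
    med = float(np.median(values))
    high = {s for s, c in counts.items() if c > med}
    low = {s for s, c in counts.items() if c <= med}
    if not high:
        warnings.warn("degenerate counts: median split puts every sample in the low group")
    return high, low


def logrank_test(
    groups: tuple[set[str], set[str]],
    times: Mapping[str, float],
    events: Mapping[str, bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed events in group 1 are
    compared with their hypergeometric expectation given the risk sets;
    tied events are handled by the simultaneous-event convention. The
    statistic is (O - E)^2 / V on 1 chi-square degree of freedom. When
    the variance is zero (e.g. identical survival in both groups) the
    statistic is 0 and p = 1.
    """
    g1, g2 = groups
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    ids = sorted(g1 | g2)
    t = np.array([times[s] for s in ids])
    e = np.array([bool(events[s]) for s in ids])
    in1 = np.array([s in g1 for s in ids])
    if not e.any():
        raise ValueError("undefined test: no events in either group")

    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for tau in event_times:
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        dying = e & (t == tau)
        d = dying.sum()
        d1 = (dying & in1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def expression_only_control(
    matrix: PresentationMatrix,
) -> tuple[set[str], set[str]]:
    """Median split on expressed-but-not-presented antigen counts.

    Patients in this split have the antigen's transcript expressed but
    lack an HLA allele predicted to present the peptide; a survival
    signal that survives here is not HLA restricted.
    """
    return median_split(matrix.expressed_not_presented_counts())


def survival_analysis(
    counts: Mapping[str, int | float],
    times: Mapping[str, float],
    events: Mapping[str, bool],
) -> dict:
    """Median split on ``counts`` followed by the log-rank test."""
    high, low = median_split(counts)
    if not high or not low:
        return {
            "n_high": len(high), "n_low": len(low),
            "statistic": float("nan"), "p": float("nan"),
            "degenerate": True,
        }
    stat, p = logrank_test((high, low), times, events)
    return {
        "n_high": len(high),
        "n_low": len(low),
        "events_high": int(sum(events[s] for s in high)),
        "events_low": int(sum(events[s] for s in low)),
        "statistic": stat,
        "p": p,
        "degenerate": False,
    }


def plot_km(
    groups: tuple[set[str], set[str]],
    times: Mapping[str, float],
    events: Mapping[str, bool],
    path: str | Path,
    labels: tuple[str, str] = ("high", "low"),
) -> None:
    """Kaplan-Meier curves for the two groups (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, label in zip(groups, labels):
        ids = sorted(group)
        kmf = KaplanMeierFitter()
        kmf.fit([times[s] for s in ids], [events[s] for s in ids], label=label)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
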