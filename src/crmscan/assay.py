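"""Enhancer-assay bookkeeping and quality control.

The injection assay drives a reporter through a minimal promoter whose
intrinsic lens expression marks successfully injected embryos.  A region
is called positive for enhancer activity when, among lens-positive
embryos, more than 50% show a reproducible expression pattern outside the
lens AND that pattern is seen in at least 10 individual fish.  Both
thresholds are applied strictly as stated (specific rate strictly above
0.5; fish count at least 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SPECIFIC_RATE_CUTOFF = 0.5  # strict: must be exceeded
MIN_SPECIFIC_FISH = 10


@dataclass(frozen=True)
class InjectionExperiment:
    region_id: str
    n_alive: int  # embryos surviving past gastrulation
    n_lens: int  # lens expression = successful injection
    n_specific: int  # reproducible non-lens expression

    def __post_init__(self) -> None:
        if not 0 <= self.n_specific <= self.n_lens <= self.n_alive:
            raise ValueError(f"{self.region_id}: need "
                             "0 <= n_specific <= n_lens <= n_alive")


@dataclass(frozen=True)
class ActivityCall:
    region_id: str
    injection_rate: float | None  # n_lens / n_alive
    specific_rate: float | None  # n_specific / n_lens
    positive: bool
    injection_failed: bool = False


def call_activity(exp: InjectionExperiment) -> ActivityCall:
    """Apply the positivity rule to one injection experiment."""
    injection_rate = exp.n_lens / exp.n_alive if exp.n_alive else None
    if exp.n_lens == 0:
        return ActivityCall(exp.region_id, injection_rate, None,
                            positive=False, injection_failed=True)
    specific_rate = exp.n_specific / exp.n_lens
    positive = (specific_rate > SPECIFIC_RATE_CUTOFF
                and exp.n_specific >= MIN_SPECIFIC_FISH)
    return ActivityCall(exp.region_id, injection_rate, specific_rate, positive)


def summarize_screen(calls: Sequence[ActivityCall]) -> dict:
    """Screen-level summary over regions with a positivity verdict."""
    if not calls:
        warnings.warn("empty screen; summary is all zeros")
        return {"n_tested": 0, "n_positive": 0, "pct_positive": 0.0,
                "mean_specific_rate": 0.0, "mean_injection_rate": 0.0}
    n_tested = len(calls)
    n_positive = sum(c.positive for c in calls)
    specific = [c.specific_rate for c in calls if c.specific_rate is not None]
    injection = [c.injection_rate for c in calls if c.injection_rate is not None]
    return {
        "n_tested": n_tested,
        "n_positive": n_positive,
        "pct_positive": 100.0 * n_positive / n_tested,
        "mean_specific_rate": sum(specific) / len(specific) if specific else 0.0,
        "mean_injection_rate": (sum(injection) / len(injection)
                                if injection else 0.0),
    }


def ontology_coverage(line_annotations: Mapping[str, Iterable[str]],
                      vocabulary: Iterable[str]) -> dict:
    """How many controlled-vocabulary terms any reporter line labels.

    The percentage is floored to an integer.  Terms outside the vocabulary
    are reported back and excluded from the count.
    """
    vocab = set(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    seen: set[str] = set()
    unknown: set[str] = set()
    for terms in line_annotations.values():
        for term in terms:
            (seen if term in vocab else unknown).add(term)
    if unknown:
        warnings.warn(f"{len(unknown)} terms outside the vocabulary excluded: "
                      f"{sorted(unknown)}")
    n_labeled = len(seen)
    return {"n_labeled": n_labeled, "n_vocabulary": len(vocab),
            "pct": int(100 * n_labeled // len(vocab)),
            "unknown_terms": sorted(unknown)}


def read_injection_table(path: str | Path) -> list[InjectionExperiment]:
    """TSV with columns region_id, n_alive, n_lens, n_specific."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [InjectionExperiment(str(r.region_id), int(r.n_alive),
                                int(r.n_lens), int(r.n_specific))
            for r in df.itertuples()]


def write_activity_table(calls: Sequence[ActivityCall], path: str | Path) -> None:
    df = pd.DataFrame([c.__dict__ for c in calls])
    df.to_csv(path, sep="\t", index=False)
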