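"""Cohort filtering and case:control-balanced splitting.

Multi-site sequencing consortia pool cohorts with very different
case:control ratios; a classifier trained on pooled genotypes can pick
up cohort signatures (platform or probe artifacts) instead of disease
signal.  The guard used here is twofold: cohorts whose minority class is
under 20% of the majority, or with fewer than 20 individuals, are
dropped; and training sets draw the same number of cases and controls
from every retained cohort, so training prevalence is exactly 0.5.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .store import SampleRecord


@dataclass
class SplitSpec:
    """Disjoint train / validation / holdout sample-id partitions."""

    train_ids: list[str]
    validation_ids: list[str]
    holdout_ids: list[str]
    per_cohort_counts: dict[str, dict[str, tuple[int, int]]]  # cohort -> part -> (cases, controls)
    seed: int

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.validation_ids), set(self.holdout_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "train_ids": self.train_ids,
                "validation_ids": self.validation_ids,
                "holdout_ids": self.holdout_ids,
                "per_cohort_counts": {c: {k: list(v) for k, v in d.items()}
                                      for c, d in self.per_cohort_counts.items()},
                "seed": self.seed,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitSpec":
        with open(path) as fh:
            d = json.load(fh)
        counts = {c: {k: tuple(v) for k, v in dd.items()}
                  for c, dd in d["per_cohort_counts"].items()}
        return cls(d["train_ids"], d["validation_ids"], d["holdout_ids"],
                   counts, d["seed"])


def filter_cohorts(samples: Sequence[SampleRecord],
                   min_minority_frac: float = 0.20,
                   min_total: int = 20) -> set[str]:
    """Retain cohorts with >= ``min_total`` individuals whose minority class
    is at least ``min_minority_frac`` of the majority class."""
    if not samples:
        raise ValueError("empty sample table")
    counts: dict[str, Counter] = {}
    for s in samples:
        counts.setdefault(s.cohort, Counter())[s.status] += 1
    retained = set()
    for cohort, c in counts.items():
        cases, controls = c["case"], c["control"]
        total = cases + controls
        if total < min_total:
            continue
        lo, hi = min(cases, controls), max(cases, controls)
        if hi == 0 or lo / hi < min_minority_frac:
            continue
        retained.add(cohort)
    return retained


def _allocate_pairs(capacity: dict[str, int], n_pairs: int) -> dict[str, int]:
    """Largest-remainder proportional allocation of case/control pairs,
    capped at each cohort's min(cases, controls) capacity."""
    total_cap = sum(capacity.values())
    if n_pairs > total_cap:
        deficit = n_pairs - total_cap
        raise ValueError(
            f"requested {n_pairs} balanced pairs but capacity is {total_cap} "
            f"(deficit {deficit}); per-cohort capacity: {capacity}")
    alloc = {c: 0 for c in capacity}
    remaining = n_pairs
    active = dict(capacity)
    while remaining > 0:
        tot = sum(active.values())
        shares = {c: remaining * cap / tot for c, cap in active.items()}
        base = {c: min(int(np.floor(v)), active[c]) for c, v in shares.items()}
        given = sum(base.values())
        # distribute leftovers by largest fractional remainder (stable order)
        rema = sorted(active, key=lambda c: (-(shares[c] - base[c]), c))
        for c in rema:
            if given >= remaining:
                break
            if base[c] < active[c]:
                base[c] += 1
                given += 1
        for c in list(active):
            alloc[c] += base[c]
            active[c] -= base[c]
            if active[c] == 0:
                del active[c]
        remaining -= given
        if given == 0:  # pragma: no cover - guarded by capacity check
            raise RuntimeError("allocation stalled")
    return alloc


def balanced_split(samples: Sequence[SampleRecord],
                   retained: set[str],
                   n_train: int,
                   n_holdout: int,
                   validation_frac: float = 0.15,
                   seed: int = 0,
                   balanced_holdout: bool = False) -> SplitSpec:
    """Draw a cohort-balanced training partition plus validation and holdout.

    The training pool takes ``n_train`` individuals, exactly half cases and
    half controls within every cohort; ``validation_frac`` of each cohort's
    pairs is carved off for early-stopping validation (balanced the same
    way).  The holdout is drawn uniformly from the remaining retained-cohort
    samples (or case:control balanced when ``balanced_holdout``).
    Deterministic given ``seed``.
    """
    if n_train % 2:
        raise ValueError("n_train must be even (case:control balanced)")
    rng = np.random.default_rng(seed)
    pool: dict[str, dict[str, list[str]]] = {}
    for s in samples:
        if s.cohort in retained:
            pool.setdefault(s.cohort, {"case": [], "control": []})[s.status].append(s.sample_id)
    capacity = {c: min(len(d["case"]), len(d["control"])) for c, d in pool.items()}
    alloc = _allocate_pairs(capacity, n_train // 2)

    train_ids, val_ids = [], []
    used: set[str] = set()
    per_cohort: dict[str, dict[str, tuple[int, int]]] = {}
    for cohort in sorted(pool):
        k = alloc.get(cohort, 0)
        n_val = int(round(k * validation_frac))
        n_tr = k - n_val
        picks = {}
        for status in ("case", "control"):
            ids = sorted(pool[cohort][status])
            picks[status] = list(rng.choice(ids, size=k, replace=False))
        train_ids += picks["case"][:n_tr] + picks["control"][:n_tr]
        val_ids += picks["case"][n_tr:] + picks["control"][n_tr:]
        used.update(picks["case"] + picks["control"])
        per_cohort[cohort] = {"train": (n_tr, n_tr), "validation": (n_val, n_val)}

    by_id = {s.sample_id: s for s in samples}
    rest = [sid for c in sorted(pool) for st in ("case", "control")
            for sid in sorted(pool[c][st]) if sid not in used]
    if balanced_holdout:
        if n_holdout % 2:
            raise ValueError("balanced holdout needs an even n_holdout")
        cases = [s for s in rest if by_id[s].status == "case"]
        controls = [s for s in rest if by_id[s].status == "control"]
        if min(len(cases), len(controls)) < n_holdout // 2:
            raise ValueError("not enough remaining samples for balanced holdout")
        holdout = (list(rng.choice(cases, n_holdout // 2, replace=False))
                   + list(rng.choice(controls, n_holdout // 2, replace=False)))
    else:
        if len(rest) < n_holdout:
            raise ValueError(
                f"holdout of {n_holdout} requested but only {len(rest)} remain")
        holdout = list(rng.choice(rest, n_holdout, replace=False))
    for sid in holdout:
        s = by_id[sid]
        d = per_cohort.setdefault(s.cohort, {})
        c, k = d.get("holdout", (0, 0))
        d["holdout"] = (c + (s.status == "case"), k + (s.status == "control"))
    return SplitSpec(train_ids, val_ids, holdout, per_cohort, seed)


def chance_cohort_accuracy(cohort_labels: Sequence[str],
                           n_draws: int = 50_000,
                           seed: int = 0) -> float:
    """Percent accuracy of guessing cohort identity uniformly at random.

    Monte-Carlo estimate of the chance floor that a cohort-identity
    classifier must beat (about 4% for 24 cohorts).
    """
    labels = np.asarray(cohort_labels)
    uniq = np.unique(labels)
    rng = np.random.default_rng(seed)
    truth = rng.choice(labels, size=n_draws, replace=True)
    guess = rng.choice(uniq, size=n_draws, replace=True)
    return 100.0 * float(np.mean(truth == guess))
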