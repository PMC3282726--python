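"""Evaluation protocols: random species-level splits, k-fold cross-validation,
success rates and Wilson confidence intervals.

Two randomization schemes are provided.  The *species-level split* keeps
every species represented in the reference library ("complete/balanced"
coverage): species with at most 3 records contribute all of them to the
reference set, larger species contribute two thirds (or as close as
possible), and the split is repeated several times with fresh randomness.
*k-fold cross-validation* partitions the whole library, so a species may be
absent from the reference side ("incomplete/unbalanced" coverage); queries
whose species is missing from the reference set — singletons — are excluded
from the success-rate denominator, since they can only be assigned wrongly.

Success counts are pooled across repetitions/folds before interval
estimation.  The confidence interval is the Wilson score interval for a
binomial proportion; printed rates follow the truncation convention
(percentages floored, not rounded, at two decimals).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from . import dv, fj, rbf
from .errors import UndefinedRateError
from .io import (
    Dataset,
    STATUS_CORRECT,
    STATUS_EXCLUDED,
    STATUS_WRONG,
    write_assignments,
)

SPECIES_LEVEL_SPLIT = "species_level_split"
K_FOLD = "k_fold"


@dataclass
class SplitPlan:
    """Reference/query index sets per repetition or fold."""

    kind: str
    splits: list[tuple[list[int], list[int]]]  # (reference, query) per rep/fold
    seed: int

    @property
    def n_rounds(self) -> int:
        return len(self.splits)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def species_level_split(
    ds: Dataset,
    ref_fraction: float = 2.0 / 3.0,
    small_species_max: int = 3,
    repetitions: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Repeated random splits at the species level (balanced coverage).

    Per repetition: species with at most ``small_species_max`` records send
    all of them to the reference set; larger species send
    ``round(ref_fraction * n)`` randomly chosen records (at least 1 left as a
    query), the rest forming the query set.  Repetition r draws from a
    generator seeded with ``seed + r``.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    table = ds.species_table
    splits = []
    for r in range(repetitions):
        rng = np.random.default_rng(seed + r)
        ref: list[int] = []
        qry: list[int] = []
        for indices in table.values():
            n = len(indices)
            if n <= small_species_max:
                ref.extend(indices)
                continue
            n_ref = _round_half_away(ref_fraction * n)
            n_ref = min(max(n_ref, 1), n - 1)
            perm = rng.permutation(n)
            ref.extend(indices[i] for i in perm[:n_ref])
            qry.extend(indices[i] for i in perm[n_ref:])
        splits.append((sorted(ref), sorted(qry)))
    return SplitPlan(SPECIES_LEVEL_SPLIT, splits, seed)


def k_fold_split(ds: Dataset, k: int = 5, seed: int = 0) -> SplitPlan:
    """k-fold partition of the whole dataset (coverage may be unbalanced).

    Records are shuffled once by ``seed`` and cut into k folds whose sizes
    differ by at most one; fold i is the query set against the union of the
    others.  Every record is queried exactly once across the k folds.
    """
    n = len(ds)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    splits = []
    for i in range(k):
        qry = sorted(int(j) for j in folds[i])
        ref = sorted(int(j) for f in folds[:i] + folds[i + 1 :] for j in f)
        splits.append((ref, qry))
    return SplitPlan(K_FOLD, splits, seed)


def success_rate(n_correct: int, n_counted: int) -> float:
    """Identification success rate n_correct / n_counted."""
    if n_counted == 0:
        raise UndefinedRateError("success rate undefined with zero counted queries")
    if not 0 <= n_correct <= n_counted:
        raise ValueError("need 0 <= n_correct <= n_counted")
    return n_correct / n_counted


def wilson_ci(n_correct: int, n_counted: int, gamma: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion at level ``gamma``.

    Inverts the normal-approximation score test: with p-hat = k/n and z the
    two-sided standard-normal quantile at level gamma,

        center = (p + z^2 / 2n) / (1 + z^2 / n)
        halfwidth = z * sqrt(p(1-p)/n + z^2 / 4n^2) / (1 + z^2 / n)

    clamped to [0, 1].
    """
    if n_counted < 1:
        raise ValueError("n_counted must be at least 1")
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    p = n_correct / n_counted
    z = float(norm.ppf((1.0 + gamma) / 2.0))
    denom = 1.0 + z * z / n_counted
    center = (p + z * z / (2 * n_counted)) / denom
    halfwidth = (
        z
        * math.sqrt(p * (1 - p) / n_counted + z * z / (4 * n_counted * n_counted))
        / denom
    )
    return max(0.0, center - halfwidth), min(1.0, center + halfwidth)


def format_percent_trunc(x: float) -> str:
    """Format a proportion as a percentage truncated (not rounded) to 2 dp.

    Display-only convention: 130/135 = 0.96296... prints as "96.29%".
    """
    if not 0 <= x <= 1:
        raise ValueError("expected a proportion in [0, 1]")
    # round at the 8th decimal first so exact values are not floored past
    # a floating-point representation error
    return f"{math.floor(round(x * 10000, 8)) / 100:.2f}%"


@dataclass
class EvaluationReport:
    """Pooled identification results for one protocol run."""

    rows: list[tuple[str, str | None, str, str]]
    protocol: str
    encoder: str
    seed: int
    n_counted: int = 0
    n_correct: int = 0
    n_excluded_singletons: int = 0
    gamma: float = 0.95
    success_rate: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Species identification report",
            "=" * 46,
            f"protocol:            {self.protocol}",
            f"encoder:             {self.encoder}",
            f"seed:                {self.seed}",
            f"queries counted:     {self.n_counted}",
            f"correct:             {self.n_correct}",
            f"excluded singletons: {self.n_excluded_singletons}",
            f"success rate:        {format_percent_trunc(self.success_rate)}",
            (
                f"{self.gamma:.0%} CI:              "
                f"{format_percent_trunc(self.ci_lower)} - "
                f"{format_percent_trunc(self.ci_upper)}"
            ),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "encoder": self.encoder,
            "seed": self.seed,
            "n_counted": self.n_counted,
            "n_correct": self.n_correct,
            "n_excluded_singletons": self.n_excluded_singletons,
            "success_rate": self.success_rate,
            "gamma": self.gamma,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "config": self.config,
        }

    def save(self, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_dict(), indent=2))
        if tsv_path is not None:
            write_assignments(self.rows, tsv_path)


ENCODERS = ("dv", "fj")


def encode_features(sequences: list[str], encoder: str) -> np.ndarray:
    """Raw per-sequence features: 24-dim DV descriptors or 5-dim FJ descriptors."""
    if encoder == "dv":
        return dv.dv_feature_matrix(sequences)
    if encoder == "fj":
        return fj.fj_feature_matrix(sequences)
    raise ValueError(f"unknown encoder {encoder!r}; expected one of {ENCODERS}")


def run_identification(
    ds: Dataset,
    plan: SplitPlan,
    encoder: str = "dv",
    spread: float = 1.0,
    pca_threshold: float = 0.01,
    gamma: float = 0.95,
    ridge: float = 0.0,
) -> EvaluationReport:
    """Run the full identification pipeline over a split plan.

    Per repetition/fold: encode the reference sequences (FJ descriptors are
    additionally reduced by a PCA fitted on the reference rows only), train
    the RBF network, classify every query.  Queries whose species is absent
    from that round's reference set are marked ``excluded_singleton`` and do
    not enter the success-rate denominator.  Counts are pooled across rounds
    before the Wilson interval is computed.
    """
    features = encode_features([rec.sequence for rec in ds], encoder)
    rows: list[tuple[str, str | None, str, str]] = []
    n_correct = n_counted = n_excluded = 0
    for ref_idx, qry_idx in plan.splits:
        if not qry_idx:
            continue
        ref_feats = features[ref_idx]
        qry_feats = features[qry_idx]
        if encoder == "fj":
            transform = fj.fit_pca(ref_feats, threshold=pca_threshold)
            ref_feats = transform.transform(ref_feats)
            qry_feats = transform.transform(qry_feats)
        ref_labels = [ds.records[i].species for i in ref_idx]
        if any(lab is None for lab in ref_labels):
            raise ValueError("reference records must all carry species labels")
        model = rbf.train_rbf(ref_feats, ref_labels, spread=spread, ridge=ridge)
        ref_species = set(ref_labels)
        predictions = rbf.predict_batch(model, qry_feats)
        for i, pred in zip(qry_idx, predictions):
            rec = ds.records[i]
            if rec.species is None or rec.species not in ref_species:
                status = STATUS_EXCLUDED
                n_excluded += 1
            elif pred == rec.species:
                status = STATUS_CORRECT
                n_correct += 1
                n_counted += 1
            else:
                status = STATUS_WRONG
                n_counted += 1
            rows.append((rec.accession, rec.species, pred, status))
    report = EvaluationReport(
        rows=rows,
        protocol=plan.kind,
        encoder=encoder,
        seed=plan.seed,
        n_counted=n_counted,
        n_correct=n_correct,
        n_excluded_singletons=n_excluded,
        gamma=gamma,
        config={"spread": spread, "pca_threshold": pca_threshold, "ridge": ridge},
    )
    if n_counted:
        report.success_rate = success_rate(n_correct, n_counted)
        report.ci_lower, report.ci_upper = wilson_ci(n_correct, n_counted, gamma)
    return report
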