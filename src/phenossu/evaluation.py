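"""Evaluation metrics: exact-span entity F1, attribute accuracies,
instance-level accuracy, Cohen's kappa, the minimum-corpus-size experiment
and instance-set comparison.

Attribute accuracy is reported three ways: per attribute category, as the
plain average over categories, and as a weighted average over attribute
values.  The value weighting is the value's share of gold support by
default ("frequency"); a "uniform" option weighs every observed value
equally, which up-weights rare values.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .recognize import PhenoSSUInstance
from .schema import PhenoSSUSchema

logger = logging.getLogger(__name__)

Span = tuple[int, int]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    per_attribute: dict[str, float]
    average_accuracy: float
    weighted_accuracy: float
    uniform_weighted_accuracy: float
    instance_accuracy: float
    value_support: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "entity": {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            "attributes": {
                "per_attribute": self.per_attribute,
                "average_accuracy": self.average_accuracy,
                "weighted_accuracy": self.weighted_accuracy,
                "uniform_weighted_accuracy": self.uniform_weighted_accuracy,
                "value_support": self.value_support,
            },
            "instance_accuracy": self.instance_accuracy,
        }

    def to_markdown(self) -> str:
        lines = [
            "# Evaluation report",
            "",
            f"- entity precision {self.precision:.3f} / recall {self.recall:.3f} "
            f"/ F1 {self.f1:.3f}",
            f"- average attribute accuracy {self.average_accuracy:.3f}",
            f"- weighted average accuracy {self.weighted_accuracy:.3f} "
            f"(uniform-over-values {self.uniform_weighted_accuracy:.3f})",
            f"- instance-level accuracy {self.instance_accuracy:.3f}",
            "",
            "| attribute | accuracy |",
            "|---|---|",
        ]
        lines += [f"| {k} | {v:.3f} |" for k, v in sorted(self.per_attribute.items())]
        return "\n".join(lines) + "\n"


def entity_f1(
    pred: list[tuple[int, int, str]], gold: list[tuple[int, int, str]]
) -> tuple[float, float, float]:
    """Exact-span, exact-type entity matching.

    A predicted entity is a true positive only when its (start, end, type)
    coincides exactly with a gold entity; matching is one-to-one.
    """
    gold_counts = Counter(gold)
    dup = sum(c - 1 for c in gold_counts.values())
    if dup:
        logger.warning("%d duplicate gold spans deduplicated", dup)
    gold_set = set(gold_counts)
    pred_counts = Counter(pred)
    tp = sum(min(1, pred_counts[g]) for g in gold_set)
    n_pred = len(set(pred_counts))
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / len(gold_set) if gold_set else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _pair_instances(
    pred: list[PhenoSSUInstance], gold: list[PhenoSSUInstance]
) -> list[tuple[PhenoSSUInstance, PhenoSSUInstance | None]]:
    """Pair gold instances with predictions: exact phenotype-span match first,
    then exact concept match for spanless gold.  Unpaired predictions are
    precision errors only and do not appear in the result."""
    by_span: dict[tuple, list[PhenoSSUInstance]] = defaultdict(list)
    by_concept: dict[str, list[PhenoSSUInstance]] = defaultdict(list)
    for p in pred:
        key = (p.doc_id, p.phenotype_span)
        by_span[key].append(p)
        by_concept[p.phenotype].append(p)
    pairs = []
    used: set[int] = set()
    for g in gold:
        match = None
        if g.phenotype_span is not None:
            for p in by_span.get((g.doc_id, g.phenotype_span), []):
                if id(p) not in used and p.phenotype == g.phenotype:
                    match = p
                    break
        else:
            for p in by_concept.get(g.phenotype, []):
                if id(p) not in used:
                    match = p
                    break
        if match is not None:
            used.add(id(match))
        pairs.append((g, match))
    return pairs


def attribute_scores(
    pred: list[PhenoSSUInstance],
    gold: list[PhenoSSUInstance],
    schema: PhenoSSUSchema | None = None,
):
    """Per-value and per-category attribute accuracy over paired instances.

    Returns ``(per_attribute, average, weighted, uniform_weighted, support)``.
    A gold slot is correct when the paired prediction assigns exactly the
    gold value; all slots of an unpaired gold instance count as wrong.
    """
    if schema is not None:
        for p in pred:
            p.validate_against(schema)
    cat_total: Counter[str] = Counter()
    cat_correct: Counter[str] = Counter()
    val_total: Counter[str] = Counter()
    val_correct: Counter[str] = Counter()
    for g, p in _pair_instances(pred, gold):
        pred_vals = p.attribute_values() if p is not None else {}
        for category, (value, _) in g.attributes.items():
            ok = pred_vals.get(category) == value
            cat_total[category] += 1
            cat_correct[category] += ok
            val_total[f"{category}={value}"] += 1
            val_correct[f"{category}={value}"] += ok
    per_attribute = {c: cat_correct[c] / cat_total[c] for c in cat_total}
    average = float(np.mean(list(per_attribute.values()))) if per_attribute else 0.0
    total = sum(val_total.values())
    weighted = (
        sum(val_correct[v] for v in val_total) / total if total else 0.0
    )
    uniform = (
        float(np.mean([val_correct[v] / val_total[v] for v in val_total]))
        if val_total
        else 0.0
    )
    return per_attribute, average, weighted, uniform, dict(val_total)


def instance_accuracy(
    pred: list[PhenoSSUInstance], gold: list[PhenoSSUInstance]
) -> float:
    """Fraction of gold instances recovered exactly (concept + all slots)."""
    if not gold:
        raise ValueError("instance accuracy undefined on empty gold")
    correct = 0
    for g, p in _pair_instances(pred, gold):
        if p is not None and p.attribute_values() == g.attribute_values():
            correct += 1
    return correct / len(gold)


def evaluate(
    pred: list[PhenoSSUInstance],
    gold: list[PhenoSSUInstance],
    pred_entities=None,
    gold_entities=None,
    schema: PhenoSSUSchema | None = None,
) -> EvalReport:
    """Full report; entity lists default to the instances' phenotype spans."""

    def spans(instances):
        return [
            (i.doc_id, *i.phenotype_span, "Phenotype")
            for i in instances
            if i.phenotype_span is not None
        ]

    p, r, f1 = entity_f1(
        pred_entities if pred_entities is not None else spans(pred),
        gold_entities if gold_entities is not None else spans(gold),
    )
    per_attr, average, weighted, uniform, support = attribute_scores(pred, gold, schema)
    return EvalReport(
        precision=p,
        recall=r,
        f1=f1,
        per_attribute=per_attr,
        average_accuracy=average,
        weighted_accuracy=weighted,
        uniform_weighted_accuracy=uniform,
        instance_accuracy=instance_accuracy(pred, gold),
        value_support=support,
    )


def cohen_kappa(labels_a: list, labels_b: list) -> float:
    """Cohen's kappa for two equal-length categorical label sequences."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if not labels_a:
        raise ValueError("empty label sequences")
    n = len(labels_a)
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    if po == 1.0:
        return 1.0
    ca, cb = Counter(labels_a), Counter(labels_b)
    pe = sum(ca[k] * cb.get(k, 0) for k in ca) / n**2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _coverage_sets(corpus: list[str], target_patterns: list) -> list[frozenset[int]]:
    compiled = []
    for p in target_patterns:
        text = getattr(p, "pattern", p)
        compiled.append(re.compile(text))
    cover = [
        frozenset(i for i, rx in enumerate(compiled) if rx.search(doc))
        for doc in corpus
    ]
    missing = set(range(len(compiled))) - frozenset().union(*cover) if cover else set(range(len(compiled)))
    if missing:
        names = [getattr(target_patterns[i], "pattern", target_patterns[i]) for i in sorted(missing)]
        raise ValueError(f"target patterns matched nowhere in the corpus: {names}")
    return cover


def min_corpus_size(
    corpus: list[str],
    target_patterns: list,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float, list[int]]:
    """Stepwise-sampling experiment: documents are added in random order and
    the count at which every target pattern has matched at least once is
    recorded; returns (mean, sd, per-repetition counts) over ``n_reps``
    seeded shuffles."""
    cover = _coverage_sets(corpus, target_patterns)
    all_targets = frozenset(range(len(target_patterns)))
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_reps):
        order = rng.permutation(len(cover))
        seen: set[int] = set()
        for k, idx in enumerate(order, start=1):
            seen |= cover[idx]
            if seen >= all_targets:
                counts.append(k)
                break
    mean = float(np.mean(counts))
    sd = float(np.std(counts))
    return mean, sd, counts


def min_corpus_size_exact(corpus: list[str], target_patterns: list) -> float:
    """Exact expectation of the stepwise-sampling count by enumerating all
    document orderings (oracle for small corpora)."""
    cover = _coverage_sets(corpus, target_patterns)
    all_targets = frozenset(range(len(target_patterns)))
    total, n_orders = 0, 0
    for order in permutations(range(len(cover))):
        seen: set[int] = set()
        for k, idx in enumerate(order, start=1):
            seen |= cover[idx]
            if seen >= all_targets:
                total += k
                break
        n_orders += 1
    return total / n_orders


def compare_instance_sets(
    set_a: list[PhenoSSUInstance], set_b: list[PhenoSSUInstance]
) -> tuple[list, list, list]:
    """Span-blind exact comparison of two instance sets.

    Instances reduce to (phenotype, attribute-value map) tuples; returns
    (shared, only_a, only_b), each sorted deterministically.
    """

    def keys(instances):
        return {
            (i.phenotype, tuple(sorted(i.attribute_values().items())))
            for i in instances
        }

    a, b = keys(set_a), keys(set_b)
    return sorted(a & b), sorted(a - b), sorted(b - a)
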