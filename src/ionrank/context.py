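"""Context classification of datasets and diversity-maximizing selection.

A context is a combination of six variables — polarity, ionization source,
mass analyzer, m/z class, sample type, and species — that characterizes a
dataset's technology and biology.  Training/testing corpora are drawn with
a fixed number of datasets per context, sampling to maximize diversity of
submitting labs and projects.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContextKey",
    "classify_mz_class",
    "group_rare_species",
    "select_datasets",
    "select_train_test",
    "MIN_CONTEXT_POOL",
]

MIN_CONTEXT_POOL = 45  # contexts with fewer datasets are ineligible

SAMPLE_TYPES = ("Tissue", "Whole Organism", "Cells", "Uncurated")


@dataclass(frozen=True)
class ContextKey:
    polarity: str
    source: str
    analyzer: str
    mz_class: str
    sample_type: str
    species: str

    def __str__(self) -> str:
        return "|".join(
            (
                self.polarity,
                self.source,
                self.analyzer,
                self.mz_class,
                self.sample_type,
                self.species,
            )
        )


def classify_mz_class(mz_min: float, mz_max: float) -> str:
    """m/z-range class: small molecules / Lipids / both.

    max <= 400 -> "small molecules"; min > 500 -> "Lipids"; datasets
    spanning both ranges -> "Lipids and small molecules".
    """
    if mz_min >= mz_max:
        raise ValueError("mz_min must be < mz_max")
    if mz_max <= 400:
        return "small molecules"
    if mz_min > 500:
        return "Lipids"
    return "Lipids and small molecules"


def group_rare_species(counts: dict[str, int]) -> dict[str, str]:
    """Map the rare tail of species to "OTHER".

    Species are sorted ascending by frequency (alphabetical tie-break);
    those whose running cumulative frequency is at most 10% of the total
    are relabeled "OTHER" (inclusive at the boundary).
    """
    total = sum(counts.values())
    if total <= 0:
        return {}
    mapping: dict[str, str] = {}
    cumulative = 0
    for species, n in sorted(counts.items(), key=lambda kv: (kv[1], kv[0])):
        cumulative += n
        mapping[species] = "OTHER" if cumulative <= 0.10 * total else species
    if len(counts) == 1:
        return {s: s for s in counts}
    return mapping


def _combo_label(meta: dict) -> tuple[str, str]:
    """(project, group) combination; missing projects get a pseudo-label.

    Datasets without a project are labeled by (submitter, submission day):
    same-day submissions by one submitter are likely replicates.
    """
    project = meta.get("project")
    if not project:
        project = f"{meta.get('submitter', '?')}@{meta.get('day', '?')}"
    return (str(project), str(meta.get("group", "?")))


def _entropy(values: list[str]) -> float:
    """Shannon entropy (bits) of a label composition."""
    counts = Counter(values)
    total = sum(counts.values())
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values() if c > 0
    )


def select_datasets(
    pool: list[dict],
    n: int = 30,
    seed: int = 0,
    min_pool: int = MIN_CONTEXT_POOL,
) -> list[str]:
    """Select ``n`` datasets from one context's pool, maximizing diversity.

    Each pool entry is a metadata dict with keys ``id``, ``group`` and
    optionally ``project``, ``submitter``, ``day``.  Phase 1 takes at least
    one dataset from every (project, group) combination (when more
    combinations exist than slots, combinations are ranked by Shannon
    entropy of their submission-day composition, then relative size,
    alphabetical last).  Phase 2 fills remaining slots from the top-ranked
    combinations, choosing datasets at random under the seed.
    """
    if len(pool) < max(n, min_pool):
        raise ValueError(
            f"context pool has {len(pool)} datasets; need >= {max(n, min_pool)}"
        )
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    combos: dict[tuple[str, str], list[dict]] = defaultdict(list)
    for meta in pool:
        combos[_combo_label(meta)].append(meta)

    def combo_rank(label: tuple[str, str]) -> tuple:
        members = combos[label]
        ent = _entropy([str(m.get("day", "?")) for m in members])
        rel_size = len(members) / len(pool)
        return (-ent, -rel_size, label)

    ranked = sorted(combos, key=combo_rank)
    selected: list[str] = []
    remaining: dict[tuple[str, str], list[dict]] = {
        label: sorted(members, key=lambda m: str(m["id"]))
        for label, members in combos.items()
    }
    # phase 1: one per combination (top-ranked combos if slots are scarce)
    for label in ranked[:n]:
        members = remaining[label]
        pick = members.pop(int(rng.integers(len(members))))
        selected.append(str(pick["id"]))
    # phase 2: fill remaining slots from top-ranked combinations
    while len(selected) < n:
        candidates = [lb for lb in ranked if remaining[lb]]
        label = min(candidates, key=combo_rank)
        members = remaining[label]
        pick = members.pop(int(rng.integers(len(members))))
        selected.append(str(pick["id"]))
    return selected


def select_train_test(
    pool: list[dict],
    n_test: int = 30,
    n_train: int = 30,
    seed: int = 0,
    min_pool: int = MIN_CONTEXT_POOL,
) -> tuple[list[str], list[str]]:
    """Mutually exclusive test and training selections from one pool.

    The test selection is drawn first and removed from the pool before the
    training selection is drawn.
    """
    test = select_datasets(pool, n=n_test, seed=seed, min_pool=min_pool)
    test_set = set(test)
    rest = [m for m in pool if str(m["id"]) not in test_set]
    train = select_datasets(rest, n=n_train, seed=seed + 1, min_pool=0)
    return train, test
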