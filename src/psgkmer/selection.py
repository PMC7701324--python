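"""Mode-wise impurity-based feature ranking and top-k selection.

The 19,876 binary descriptors fall into four generation modes:

* A — ungapped position-specific k-mers (FT1-FT3),
* B — monomer-gap-dimer patterns (FT4-FT6),
* C — dimer-gap-monomer patterns (FT7-FT9),
* D — monomer-gap-monomer-gap-monomer patterns (FT10).

Ranking the whole space with one forest lets correlated descriptors from
one mode crowd out the rest, so an independent random forest is trained
per mode and the top k of each (default 100) are combined; GC-content is
preselected and bypasses ranking, giving 4k + 1 = 401 features.
Importance is mean decrease in Gini impurity averaged over the forest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .encoder import GC_NAME, FeatureMatrix

#: mode group -> member feature types; GC (FT11) belongs to no group
MODE_GROUPS: dict[str, tuple[str, ...]] = {
    "A": ("FT1", "FT2", "FT3"),
    "B": ("FT4", "FT5", "FT6"),
    "C": ("FT7", "FT8", "FT9"),
    "D": ("FT10",),
}


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the per-mode ranking forests.

    Conventional defaults: 100 unpruned trees, Gini criterion, bootstrap
    resampling, sqrt(group size) candidate splitters per node.  The
    selection contract is the ranking protocol, not a particular forest.
    """

    n_trees: int = 100
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True


def group_indices(matrix: FeatureMatrix) -> dict[str, np.ndarray]:
    """Canonical descriptor indices per mode group (ascending)."""
    by_type: dict[str, list[int]] = {}
    for d in matrix.descriptors:
        by_type.setdefault(d.feature_type, []).append(d.index)
    out = {}
    for g, fts in MODE_GROUPS.items():
        members = sorted(i for ft in fts for i in by_type.get(ft, []))
        out[g] = np.array(members, dtype=int)
    return out


def rank_group(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    seed: int,
    forest: ForestConfig = ForestConfig(),
) -> np.ndarray:
    """Mean-decrease-in-impurity importances for one group's columns.

    ``matrix`` must already be restricted to the group.  Importances are
    non-negative and reproducible for a fixed seed.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking requires both classes present")
    if matrix.n_features == 0:
        raise ValueError("empty feature group")
    rf = RandomForestClassifier(
        n_estimators=forest.n_trees,
        criterion="gini",
        max_depth=forest.max_depth,
        max_features=forest.max_features,
        bootstrap=forest.bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(matrix.values, labels)
    return rf.feature_importances_


def select_top(importances: np.ndarray, k: int) -> np.ndarray:
    """Positions of the k highest importances, ties broken by ascending
    position; output sorted ascending (canonical order)."""
    importances = np.asarray(importances, dtype=float)
    if k > len(importances):
        raise ValueError(
            f"k={k} exceeds group size {len(importances)}"
        )
    # stable sort on -importance keeps lower positions first among ties
    order = np.argsort(-importances, kind="stable")[:k]
    return np.sort(order)


@dataclass
class SelectionResult:
    """Outcome of a group-wise selection run."""

    k: int
    seed: int
    group_importances: dict[str, np.ndarray]
    group_selected: dict[str, list[str]]
    selected_names: list[str]
    training_fingerprint: str
    forest: ForestConfig = field(default_factory=ForestConfig)

    @property
    def selected_binary_names(self) -> list[str]:
        return [n for n in self.selected_names if n != GC_NAME]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "forest": {
                "n_trees": self.forest.n_trees,
                "max_depth": self.forest.max_depth,
                "max_features": self.forest.max_features,
                "bootstrap": self.forest.bootstrap,
            },
            "training_fingerprint": self.training_fingerprint,
            "group_importance_summary": {
                g: {
                    "n": int(len(v)),
                    "max": float(v.max()),
                    "mean": float(v.mean()),
                }
                for g, v in self.group_importances.items()
            },
            "group_selected": self.group_selected,
            "selected_names": self.selected_names,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _fingerprint(matrix: FeatureMatrix, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    for sid, y in zip(matrix.sample_ids, labels):
        h.update(f"{sid}:{int(y)};".encode())
    return h.hexdigest()[:16]


def groupwise_select(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    k: int = 100,
    seed: int = 0,
    forest: ForestConfig = ForestConfig(),
) -> SelectionResult:
    """Rank each mode group with its own forest and keep the top k of each.

    GC-content is preselected and never counted toward k; the combined
    set therefore has 4k + 1 members.  Callers must pass training rows
    only — the selection touches nothing else.
    """
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels required for selection")
    labels = np.asarray(labels, dtype=int)
    groups = group_indices(matrix)
    if any(len(v) == 0 for v in groups.values()):
        empty = [g for g, v in groups.items() if len(v) == 0]
        raise ValueError(f"matrix lacks descriptors for mode group(s) {empty}")

    ss = np.random.SeedSequence(seed)
    group_seeds = {
        g: int(s.generate_state(1)[0] % (2**31))
        for g, s in zip(sorted(groups), ss.spawn(len(groups)))
    }

    importances: dict[str, np.ndarray] = {}
    selected: dict[str, list[str]] = {}
    combined: list[int] = []
    for g in sorted(groups):
        idx = groups[g]
        sub = matrix.select_columns(idx)
        imp = rank_group(sub, labels, group_seeds[g], forest)
        importances[g] = imp
        top_local = select_top(imp, k)
        chosen = idx[top_local]
        selected[g] = [matrix.descriptors[i].name for i in chosen]
        combined.extend(int(i) for i in chosen)

    gc_index = matrix.column_index(GC_NAME)
    combined.append(gc_index)
    combined_sorted = sorted(set(combined))
    if len(combined_sorted) != 4 * k + 1:
        raise AssertionError("mode groups overlapped; selection is corrupt")
    names = [matrix.descriptors[i].name for i in combined_sorted]
    return SelectionResult(
        k=k,
        seed=seed,
        group_importances=importances,
        group_selected=selected,
        selected_names=names,
        training_fingerprint=_fingerprint(matrix, labels),
        forest=forest,
    )


def stable_intersection(results: list[SelectionResult]) -> list[str]:
    """Descriptors present in every combined selected set, GC excluded.

    Used to find patterns that survive selection across all folds and
    repeats of a cross-validation — the stable, presumably biologically
    meaningful descriptors.  Names carry the pattern template and the
    1-based start-end positions.
    """
    if len(results) < 2:
        raise ValueError("need at least two selection results to intersect")
    universes = {tuple(sorted(r.group_importances)) for r in results}
    sizes = {
        tuple(len(v) for _, v in sorted(r.group_importances.items()))
        for r in results
    }
    if len(universes) != 1 or len(sizes) != 1:
        raise ValueError("selection results cover different descriptor universes")
    common = set(results[0].selected_binary_names)
    for r in results[1:]:
        common &= set(r.selected_binary_names)
    # report in canonical column order (first result's ordering)
    order = {n: i for i, n in enumerate(results[0].selected_names)}
    return sorted(common, key=lambda n: order.get(n, 1 << 30))
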