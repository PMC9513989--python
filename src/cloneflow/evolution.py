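"""Clone lineage assembly under the pigeonhole sum rule.

Given a clusters x stages cellular-prevalence matrix, build a rooted clone
tree such that in every stage (i) an ancestor's prevalence is at least a
descendant's and (ii) a parent's prevalence is at least the sum of its
children's.  Attachment is greedy — clusters in order of decreasing total
prevalence, each attached to the placed node of smallest prevalence that
keeps both rules within a tolerance — which is deterministic and, for the
handful of clusters a single patient yields, routinely agrees with
exhaustive search (the test suite checks this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CloneTree",
    "build_tree",
    "classify_timing",
    "fishplot_table",
    "exhaustive_trees",
    "ROOT",
]

ROOT = -1  # the normal-cell root; prevalence 1 in every stage


@dataclass
class CloneTree:
    """Rooted clone lineage with per-stage prevalences.

    ``parent`` maps cluster id -> parent cluster id (ROOT = -1 for the
    normal-cell root).  ``violations`` lists (node, stage, excess) triples
    where no attachment could satisfy the rules; an empty list means the
    tree is consistent within ``eps``.
    """

    parent: dict[int, int]
    prevalence: pd.DataFrame  # clusters x stages, NaN treated as 0
    eps: float = 0.05
    violations: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def is_consistent(self) -> bool:
        return not self.violations

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def check(self) -> list[tuple[int, str, float]]:
        """Re-verify sum and ancestry rules; returns violations found."""
        phi = self.prevalence.fillna(0.0)
        out = []
        for node in [ROOT, *self.parent]:
            kids = self.children(node)
            if not kids:
                continue
            for stage in phi.columns:
                parent_phi = 1.0 if node == ROOT else float(phi.at[node, stage])
                ssum = float(phi.loc[kids, stage].sum())
                if ssum > parent_phi + self.eps:
                    out.append((node, stage, ssum - parent_phi))
                for k in kids:
                    if float(phi.at[k, stage]) > parent_phi + self.eps:
                        out.append((k, stage, float(phi.at[k, stage]) - parent_phi))
        return out


def _valid_parent(
    phi: np.ndarray, stages: int, child: int, parent: int, kids_of: dict[int, list[int]], eps: float
) -> bool:
    for s in range(stages):
        p_phi = 1.0 if parent == ROOT else phi[parent, s]
        if phi[child, s] > p_phi + eps:  # ancestry rule
            return False
        ssum = sum(phi[k, s] for k in kids_of.get(parent, [])) + phi[child, s]
        if ssum > p_phi + eps:  # sum rule
            return False
    return True


def build_tree(prevalence_matrix: pd.DataFrame, eps: float = 0.05) -> CloneTree:
    """Greedy clone-tree construction from a clusters x stages matrix.

    Missing entries are treated as prevalence 0 for ordering and rule
    checks.  When even the root cannot legally adopt a cluster (its
    siblings already exhaust the root's mass), the cluster is attached to
    the root anyway and the violation recorded — the caller receives a
    structured report rather than an exception.
    """
    phi_df = prevalence_matrix.fillna(0.0)
    clusters = list(phi_df.index)
    stages = list(phi_df.columns)
    phi = {c: phi_df.loc[c].to_numpy(dtype=float) for c in clusters}
    order = sorted(clusters, key=lambda c: (-phi[c].sum(), c))

    arr = phi_df.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(clusters)}
    S = len(stages)
    parent: dict[int, int] = {}
    kids_of: dict[int, list[int]] = {}
    violations: list[tuple[int, str, float]] = []

    for c in order:
        placed = [n for n in order if n in parent] + [ROOT]
        candidates = []
        for cand in placed:
            if cand == c:
                continue
            ok = True
            for s in range(S):
                p_phi = 1.0 if cand == ROOT else arr[pos[cand], s]
                if arr[pos[c], s] > p_phi + eps:
                    ok = False
                    break
                ssum = sum(arr[pos[k], s] for k in kids_of.get(cand, [])) + arr[pos[c], s]
                if ssum > p_phi + eps:
                    ok = False
                    break
            if ok:
                cand_phi = 1.0 + S if cand == ROOT else arr[pos[cand]].sum()
                candidates.append((cand_phi, cand))
        if candidates:
            # smallest-prevalence valid parent; root is the fallback (largest)
            _, chosen = min(candidates, key=lambda t: (t[0], t[1]))
        else:
            chosen = ROOT
            for s in range(S):
                ssum = sum(arr[pos[k], s] for k in kids_of.get(ROOT, [])) + arr[pos[c], s]
                if ssum > 1.0 + eps:
                    violations.append((c, stages[s], ssum - 1.0))
                if arr[pos[c], s] > 1.0 + eps:
                    violations.append((c, stages[s], arr[pos[c], s] - 1.0))
        parent[c] = chosen
        kids_of.setdefault(chosen, []).append(c)

    return CloneTree(parent=parent, prevalence=prevalence_matrix, eps=eps, violations=violations)


def exhaustive_trees(prevalence_matrix: pd.DataFrame, eps: float = 0.05) -> list[dict[int, int]]:
    """All rule-satisfying parent maps, by brute force (intended for <= 7 clusters).

    Enumerates every function parent: cluster -> {ROOT} u clusters, keeps
    the acyclic ones, and checks both rules in every stage.  Serves as the
    oracle the greedy construction is tested against.
    """
    phi_df = prevalence_matrix.fillna(0.0)
    clusters = list(phi_df.index)
    if len(clusters) > 7:
        raise ValueError("exhaustive search is for <= 7 clusters")
    arr = phi_df.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(clusters)}
    S = arr.shape[1]
    out = []

    def acyclic(parent: dict[int, int]) -> bool:
        for c in clusters:
            seen = set()
            while c != ROOT:
                if c in seen:
                    return False
                seen.add(c)
                c = parent[c]
        return True

    choices = [[ROOT] + [p for p in clusters if p != c] for c in clusters]
    idx = [0] * len(clusters)
    total = int(np.prod([len(ch) for ch in choices]))
    for t in range(total):
        rem, parent = t, {}
        for i, c in enumerate(clusters):
            parent[c] = choices[i][rem % len(choices[i])]
            rem //= len(choices[i])
        if not acyclic(parent):
            continue
        ok = True
        for node in [ROOT, *clusters]:
            kids = [c for c in clusters if parent[c] == node]
            if not kids:
                continue
            for s in range(S):
                p_phi = 1.0 if node == ROOT else arr[pos[node], s]
                if sum(arr[pos[k], s] for k in kids) > p_phi + eps:
                    ok = False
                    break
                if any(arr[pos[k], s] > p_phi + eps for k in kids):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(parent)
    return out


def classify_timing(
    prevalence_matrix: pd.DataFrame,
    present_thresh: float = 0.10,
    absent_thresh: float = 0.02,
) -> pd.Series:
    """Timing class per cluster from its stage trajectory.

    With P = present (phi >= present_thresh) and A = absent
    (phi <= absent_thresh), per ordered stages:

    - ``shared``: P in every stage;
    - ``stage_specific:<stage>``: P in exactly one stage, A elsewhere;
    - ``emergent_at:<stage>``: A before some stage, P from it onward;
    - ``vanished_after:<stage>``: P up to some stage, A strictly after;
    - ``unclassified`` otherwise (including phi between the thresholds).

    Missing entries count as absent.
    """
    if not 0.0 <= absent_thresh < present_thresh <= 1.0:
        raise ValueError(
            f"need 0 <= absent_thresh < present_thresh <= 1, got "
            f"({absent_thresh}, {present_thresh})"
        )
    phi = prevalence_matrix.fillna(0.0)
    stages = list(phi.columns)
    labels = {}
    for c in phi.index:
        row = phi.loc[c].to_numpy(dtype=float)
        present = row >= present_thresh
        absent = row <= absent_thresh
        if present.all():
            labels[c] = "shared"
        elif present.sum() == 1 and (absent | present).all():
            labels[c] = f"stage_specific:{stages[int(np.argmax(present))]}"
        else:
            labels[c] = _ramp_label(present, absent, stages)
    return pd.Series(labels, name="timing")


def _ramp_label(present: np.ndarray, absent: np.ndarray, stages: list[str]) -> str:
    n = len(stages)
    for s in range(1, n):  # emergent_at: absent before s, present from s on
        if absent[:s].all() and present[s:].all():
            return f"emergent_at:{stages[s]}"
    for s in range(n - 1):  # vanished_after: present through s, absent after
        if present[: s + 1].all() and absent[s + 1 :].all():
            return f"vanished_after:{stages[s]}"
    return "unclassified"


def fishplot_table(tree: CloneTree) -> pd.DataFrame:
    """Long-format (stage, clone, prevalence, parent) table for fishplots.

    ``prevalence`` passes the tree's phi-hat through unchanged;
    ``plot_prevalence`` rescales children proportionally wherever they
    overflow their parent (possible within eps), so nested drawing
    intervals always fit.
    """
    phi = tree.prevalence.fillna(0.0)
    stages = list(phi.columns)
    plot_phi = phi.copy().astype(float)

    def rescale(node: int) -> None:
        kids = tree.children(node)
        if not kids:
            return
        for stage in stages:
            parent_phi = 1.0 if node == ROOT else float(plot_phi.at[node, stage])
            ssum = float(plot_phi.loc[kids, stage].sum())
            if ssum > parent_phi and ssum > 0:
                plot_phi.loc[kids, stage] *= parent_phi / ssum
        for k in kids:
            rescale(k)

    rescale(ROOT)
    rows = []
    for clone in phi.index:
        for stage in stages:
            rows.append(
                {
                    "stage": stage,
                    "clone": clone,
                    "prevalence": float(phi.at[clone, stage]),
                    "plot_prevalence": float(plot_phi.at[clone, stage]),
                    "parent": tree.parent[clone],
                }
            )
    return pd.DataFrame(rows, columns=["stage", "clone", "prevalence", "plot_prevalence", "parent"])
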