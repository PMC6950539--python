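"""Network-constrained, mutual-information-based direction-of-change calls.

For each metabolite (the *anchor*), the algorithm enumerates small connected
groups of network neighbors containing the anchor, scores each group by the
mutual information between its joint concentrations and the binary class
label (a k-nearest-neighbor mixed continuous/discrete estimator), keeps the
most informative group as evidence, and calls the anchor "up", "down" or "="
by comparing its class-conditional expected levels.  Expected levels are
geometric means (exponentiated mean log-concentration) by default, so the
relative threshold ``epsilon`` acts on fold change.  A pooled-z significance
gate keeps sampling noise from producing spurious non-"=" calls at cohort
scale; ``min_z=0`` disables it and recovers the plain epsilon rule.

Applied across the seven clinical contrasts this produces the metabolite x
contrast direction matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .panel import MetabolicNetwork, default_network, default_panel

log = logging.getLogger(__name__)

__all__ = [
    "MetaboliteGroup",
    "DirectionCall",
    "DirectionMatrix",
    "enumerate_groups",
    "estimate_mi",
    "predict_direction",
    "run_adema",
    "DEFAULT_CONTRASTS",
]

#: contrast name -> (manifest field, case value, control value); orientation
#: is case-first, so "up" means higher in the case group
DEFAULT_CONTRASTS = {
    "tumor_grade": ("grade", "G1", "G2"),
    "perineural_invasion": ("perineural_invasion", "yes", "no"),
    "angioinvasion": ("angioinvasion", "yes", "no"),
    "parietal_infiltration": ("parietal_infiltration", "deep", "superficial"),
    "tumor_secretion": ("functional", True, False),
    "metastases_at_diagnosis": ("metastatic", True, False),
    "multifocality": ("multifocal", True, False),
}

DEFAULT_EPSILON = 0.05
DEFAULT_MIN_Z = 1.75
DEFAULT_MI_K = 3
DEFAULT_GROUP_SIZE = 3


@dataclass(frozen=True)
class MetaboliteGroup:
    """A connected set of metabolites informing one anchor's call."""

    anchor: str
    members: tuple[str, ...]

    def __post_init__(self):
        if self.anchor not in self.members:
            raise ValueError("group must contain its anchor")


@dataclass
class DirectionCall:
    metabolite: str
    contrast: str
    call: str  # up | down | same
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.call not in ("up", "down", "same"):
            raise ValueError(f"invalid call {self.call!r}")


def enumerate_groups(
    net: MetabolicNetwork, k: int = DEFAULT_GROUP_SIZE
) -> dict[str, list[MetaboliteGroup]]:
    """Anchor -> its candidate groups: the singleton plus every subset of the
    anchor's neighborhood of size <= k that contains the anchor (all such
    subsets are connected through the anchor).  Deterministic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[MetaboliteGroup]] = {}
    for anchor in net.nodes:
        nbrs = net.neighbors(anchor)
        groups = [MetaboliteGroup(anchor, (anchor,))]
        for size in range(1, k):
            for extra in combinations(nbrs, size):
                groups.append(
                    MetaboliteGroup(anchor, tuple(sorted((anchor,) + extra)))
                )
        out[anchor] = groups
    return out


def estimate_mi(values: np.ndarray, labels: np.ndarray,
                k: int = DEFAULT_MI_K) -> float:
    """Mutual information I(values; class) in bits.

    k-nearest-neighbor estimator for continuous features and a discrete
    class (Chebyshev metric): for each point, the distance to its k-th
    within-class neighbor defines a radius; counting all-class neighbors
    inside that radius gives
    I = psi(N) - <psi(N_class)> + psi(k) - <psi(m_i)>.
    Degenerate (constant) values give 0; the estimate is clamped at 0.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need >= 3 samples per class")
    if np.all(np.ptp(X, axis=0) == 0):
        return 0.0
    k = int(min(k, counts.min() - 1))
    radius = np.empty(n)
    for c in classes:
        mask = y == c
        tree = cKDTree(X[mask])
        # k+1 because the query point is its own nearest neighbor
        d, _ = tree.query(X[mask], k=k + 1, p=np.inf)
        radius[mask] = d[:, -1]
    full = cKDTree(X)
    nz = radius > 0
    # m_i: neighbors of any class strictly inside the k-th same-class
    # distance, excluding the point itself
    m = np.full(n, float(k) - 1)
    if nz.any():
        m[nz] = [
            len(full.query_ball_point(X[i], radius[i] * (1 - 1e-10), p=np.inf)) - 1
            for i in np.flatnonzero(nz)
        ]
        m[nz] = np.maximum(m[nz], 1)
    n_class = pd.Series(y).map(dict(zip(classes, counts))).to_numpy(dtype=float)
    mi_nats = digamma(n) - np.mean(digamma(n_class)) + digamma(k) \
        - np.mean(digamma(m + 1))
    return max(float(mi_nats) / np.log(2), 0.0)


def _expected_levels(x_case: np.ndarray, x_control: np.ndarray,
                     log_scale: bool) -> tuple[float, float]:
    if log_scale:
        return (float(np.exp(np.mean(np.log(x_case)))),
                float(np.exp(np.mean(np.log(x_control)))))
    return float(np.mean(x_case)), float(np.mean(x_control))


def predict_direction(
    anchor: str,
    groups: list[MetaboliteGroup],
    values: pd.DataFrame,
    labels: pd.Series,
    epsilon: float = DEFAULT_EPSILON,
    min_z: float = DEFAULT_MIN_Z,
    mi_k: int = DEFAULT_MI_K,
    log_scale: bool = True,
    contrast: str = "",
) -> DirectionCall:
    """Call the anchor's expected direction of change (case vs control).

    The most informative group (max MI) is recorded as evidence; the call
    compares the anchor's class-conditional expected levels with the
    relative threshold ``epsilon`` (a boundary exactly at epsilon stays
    "same") and, when ``min_z > 0``, additionally requires the pooled-z of
    the (log-scale) mean difference to clear ``min_z``.
    """
    groups = [g for g in groups if g.anchor == anchor]
    if not groups:
        raise ValueError(f"no groups for anchor {anchor!r}")
    case_mask = labels.to_numpy() == True  # noqa: E712 - labels are 0/1 or bool
    Xlog = np.log(values.to_numpy(dtype=float)) if log_scale \
        else values.to_numpy(dtype=float)
    cols = {m: i for i, m in enumerate(values.columns)}
    y = case_mask.astype(int)
    best_group, best_mi = groups[0], -1.0
    for g in groups:
        sub = Xlog[:, [cols[m] for m in g.members]]
        mi = estimate_mi(sub, y, k=mi_k)
        if mi > best_mi + 1e-12:
            best_group, best_mi = g, mi
    xa = values[anchor].to_numpy(dtype=float)
    case_level, control_level = _expected_levels(
        xa[case_mask], xa[~case_mask], log_scale
    )
    la = Xlog[:, cols[anchor]]
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    sp2 = (
        (n1 - 1) * la[case_mask].var(ddof=1)
        + (n2 - 1) * la[~case_mask].var(ddof=1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    z = (la[case_mask].mean() - la[~case_mask].mean()) / se if se > 0 else 0.0
    rel = case_level / control_level - 1.0 if control_level > 0 else 0.0
    call = "same"
    if rel > epsilon and z > min_z:
        call = "up"
    elif rel < -epsilon and z < -min_z:
        call = "down"
    return DirectionCall(
        metabolite=anchor,
        contrast=contrast,
        call=call,
        evidence={
            "group": list(best_group.members),
            "mi_bits": best_mi,
            "case_level": case_level,
            "control_level": control_level,
            "z": float(z),
            "n_case": n1,
            "n_control": n2,
            "mi_k": mi_k,
            "epsilon": epsilon,
            "min_z": min_z,
        },
    )


@dataclass
class DirectionMatrix:
    """Metabolite x contrast grid of direction calls ('up' / 'down' / '=')."""

    calls: pd.DataFrame
    evidence: dict[str, dict[str, dict]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        df = self.calls.copy()
        df.index.name = "metabolite"
        df.to_csv(path)

    def dump_evidence(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.evidence, indent=2, default=float))


def run_adema(
    qt: pd.DataFrame,
    manifest: pd.DataFrame,
    net: MetabolicNetwork | None = None,
    contrasts: dict[str, tuple] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    min_z: float = DEFAULT_MIN_Z,
    mi_k: int = DEFAULT_MI_K,
    group_size: int = DEFAULT_GROUP_SIZE,
    log_scale: bool = True,
) -> DirectionMatrix:
    """Direction matrix over the default seven clinical contrasts.

    Contrasts run on primary-tumor samples; samples with a missing covariate
    are excluded per contrast, and a contrast with an empty side is skipped
    with a warning.  Cells use the three-symbol alphabet up / down / '='.
    """
    net = net or default_network()
    contrasts = contrasts or DEFAULT_CONTRASTS
    groups = enumerate_groups(net, k=group_size)
    meta = manifest.set_index("sample_id")
    primary = meta[meta.tissue_class == "primary_tumor"]
    metabolites = [m for m in qt.columns]
    calls = pd.DataFrame("=", index=metabolites,
                         columns=list(contrasts.keys()), dtype=object)
    evidence: dict[str, dict[str, dict]] = {}
    kept_cols = []
    for cname, (fld, case_value, control_value) in contrasts.items():
        vals = primary[fld]
        is_case = vals == case_value
        is_control = vals == control_value
        ids = primary.index[(is_case | is_control)]
        ids = ids[ids.isin(qt.index)]
        labels = (vals.loc[ids] == case_value)
        if labels.sum() < 3 or (~labels).sum() < 3:
            log.warning("contrast %s skipped: empty or too-small side "
                        "(MI needs >= 3 samples per class)", cname)
            calls.drop(columns=cname, inplace=True)
            continue
        kept_cols.append(cname)
        sub = qt.loc[ids, metabolites]
        evidence[cname] = {}
        for anchor in metabolites:
            dc = predict_direction(
                anchor, groups.get(anchor, []), sub, labels,
                epsilon=epsilon, min_z=min_z, mi_k=mi_k,
                log_scale=log_scale, contrast=cname,
            )
            calls.loc[anchor, cname] = {"up": "up", "down": "down",
                                        "same": "="}[dc.call]
            evidence[cname][anchor] = dc.evidence
    return DirectionMatrix(calls=calls, evidence=evidence)
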