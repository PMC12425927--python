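"""Ordination-derived β-diversity and community-structure response ratios.

Published studies report community dissimilarity as 2D ordination plots
(NMDS, PCA, PCoA, RDA).  Given the sample coordinates on the first two
axes, within- and between-group mean Euclidean distances summarize the
dispersion of each group (monoculture control vs intercropping treatment)
and their separation:

    D_c  mean pairwise distance among control samples
    D_t  mean pairwise distance among treatment samples
    D_b  mean pairwise distance across the two groups

β-diversity response:   lnRRb = ln(D_t / D_c)  — a dispersion ratio.
Structure response, two conventions:
    "as_printed"      lnRRs = ln(D_t / (D_c + D_t)); always negative for
                      positive distances, retained for auditability.
    "between_within"  lnRRs = ln(D_b / ((D_c + D_t)/2)); between-group
                      separation against mean within-group dispersion,
                      positive when the groups separate.  This is the
                      default: reported structure effects are large and
                      positive, which only a separation-based contrast
                      can produce.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

GROUPS = ("control", "treatment")
METHODS = frozenset({"NMDS", "PCA", "PCoA", "RDA"})


@dataclass
class OrdinationSet:
    """2D ordination coordinates for one paired observation."""

    obs_id: str
    method: str
    sample_ids: list[str]
    groups: np.ndarray      # array of "control"/"treatment", shape (n,)
    coords: np.ndarray      # shape (n, 2)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sample_ids)
        if self.coords.shape != (n, 2) or self.groups.shape != (n,):
            raise ValueError("sample_ids, groups and coords must align; coords must be 2D")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_id values must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.method not in METHODS:
            raise ValueError(f"unknown ordination method {self.method!r}")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")
        for g in GROUPS:
            if int(np.sum(self.groups == g)) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")


@dataclass(frozen=True)
class StructureDistances:
    """Mean pairwise Euclidean distances within and between groups."""

    d_within_ctrl: float
    d_within_treat: float
    d_between: float
    degenerate: bool = False  # some within-group point set collapsed to one point


def pairwise_euclidean(oset: OrdinationSet) -> np.ndarray:
    """Symmetric Euclidean distance matrix over all samples."""
    if len(oset.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    return squareform(pdist(oset.coords, metric="euclidean"))


def summarize_distances(oset: OrdinationSet) -> StructureDistances:
    """Mean distances over control pairs, treatment pairs and cross pairs.

    Each unordered pair is counted once.  A group whose points coincide
    yields a within distance of 0 and is flagged degenerate.
    """
    dist = pairwise_euclidean(oset)
    ctrl = np.flatnonzero(oset.groups == "control")
    treat = np.flatnonzero(oset.groups == "treatment")

    def mean_within(idx: np.ndarray) -> float:
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())

    d_c = mean_within(ctrl)
    d_t = mean_within(treat)
    d_b = float(dist[np.ix_(ctrl, treat)].mean())
    degenerate = d_c == 0.0 or d_t == 0.0
    if degenerate:
        logger.warning("summarize_distances(%s): degenerate group (zero within-group distance)",
                       oset.obs_id)
    return StructureDistances(d_c, d_t, d_b, degenerate)


def lnrr_beta(d: StructureDistances) -> float:
    """β-diversity response ratio: ln of the within-group dispersion ratio."""
    if d.d_within_treat <= 0 or d.d_within_ctrl <= 0:
        raise ValueError("lnRRb undefined: zero within-group distance")
    return math.log(d.d_within_treat / d.d_within_ctrl)


def lnrr_structure(d: StructureDistances, convention: str = "between_within") -> float:
    """Community-structure response ratio under the chosen convention."""
    if convention == "as_printed":
        denom = d.d_within_ctrl + d.d_within_treat
        if d.d_within_treat <= 0 or denom <= 0:
            raise ValueError("lnRRs undefined: zero distance in ratio")
        return math.log(d.d_within_treat / denom)
    if convention == "between_within":
        denom = (d.d_within_ctrl + d.d_within_treat) / 2.0
        if d.d_between <= 0 or denom <= 0:
            raise ValueError("lnRRs undefined: zero distance in ratio")
        return math.log(d.d_between / denom)
    raise ValueError(f"unknown lnRRs convention {convention!r}")


def load_ordination_csv(path: str | Path) -> list[OrdinationSet]:
    """Read coordinate CSV (obs_id, sample_id, group, axis1, axis2, method)."""
    expected = ["obs_id", "sample_id", "group", "axis1", "axis2", "method"]
    rows: dict[str, dict[str, list]] = {}
    order: list[str] = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != expected:
            raise ValueError(f"{path}: expected header {expected}, got {reader.fieldnames}")
        for record in reader:
            obs_id = record["obs_id"]
            if obs_id not in rows:
                rows[obs_id] = {"sample_ids": [], "groups": [], "coords": [], "method": []}
                order.append(obs_id)
            rows[obs_id]["sample_ids"].append(record["sample_id"])
            rows[obs_id]["groups"].append(record["group"])
            rows[obs_id]["coords"].append((float(record["axis1"]), float(record["axis2"])))
            rows[obs_id]["method"].append(record["method"])
    sets = []
    for obs_id in order:
        data = rows[obs_id]
        methods = set(data["method"])
        if len(methods) != 1:
            raise ValueError(f"{path}: obs_id {obs_id!r} mixes ordination methods {methods}")
        sets.append(OrdinationSet(
            obs_id=obs_id,
            method=methods.pop(),
            sample_ids=data["sample_ids"],
            groups=np.array(data["groups"], dtype=object),
            coords=np.array(data["coords"], dtype=float),
        ))
    return sets


def write_ordination_csv(sets: list[OrdinationSet], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["obs_id", "sample_id", "group", "axis1", "axis2", "method"])
        for oset in sets:
            for sid, grp, (a1, a2) in zip(oset.sample_ids, oset.groups, oset.coords):
                writer.writerow([oset.obs_id, sid, grp, repr(float(a1)), repr(float(a2)), oset.method])
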