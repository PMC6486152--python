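"""Lineage forests, fate-class assignment and family intensity summaries.

A tracked movie is represented as a forest over cell-frame observations:
every observation at frame t > 0 has exactly one predecessor at frame t-1
(the same cell, or the parent of a division), and the cells present at frame
0 are the founders.  A *family* is a founder together with all of its
descendants.  Families are classified by the founder's inner/outer position
at frame 0 and the positions of its leaves at the movie's final frame:

=====================  ==========================  ============
founder at frame 0     leaves at final frame        class
=====================  ==========================  ============
inner                  all inner                   IN-ICM
inner                  mixed                       IN-TE+ICM
outer                  all outer                   OUT-TE
outer                  mixed                       OUT-TE+ICM
either                 opposite side only          OTHER (flagged)
either                 no surviving leaves         UNCLASSIFIABLE (flagged)
=====================  ==========================  ============

The two OTHER patterns are not covered by the four named classes and are
flagged rather than silently merged.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LineageForest",
    "ForestError",
    "build_forest",
    "classify_families",
    "family_mean_trajectory",
    "initial_intensity",
    "position_change_summary",
    "read_trackmate_xml",
    "FAMILY_CLASSES",
]

FAMILY_CLASSES = ("IN-ICM", "IN-TE+ICM", "OUT-TE", "OUT-TE+ICM", "OTHER",
                  "UNCLASSIFIABLE")

Node = tuple  # (embryo_id, cell_id, frame)


class ForestError(ValueError):
    """Malformed tracking input (cycle, multiple parents, missing node)."""


@dataclass
class LineageForest:
    """Forest of cell-frame observations for one or more embryos."""

    nodes: set
    parent: dict            # node -> predecessor node
    children: dict          # node -> list of successor nodes
    founders: list          # nodes at frame 0
    family_of: dict         # node -> founder node
    final_frame: dict       # embryo_id -> last frame index
    orphans: list = field(default_factory=list)

    def families(self) -> dict:
        """founder node -> sorted list of member nodes."""
        fams: dict = {f: [] for f in self.founders}
        for n, f in self.family_of.items():
            fams[f].append(n)
        for f in fams:
            fams[f].sort(key=lambda n: (n[2], str(n[1])))
        return fams

    def leaves(self, founder: Node) -> list:
        """Family members observed at the movie's final frame."""
        last = self.final_frame[founder[0]]
        return [
            n for n, f in self.family_of.items()
            if f == founder and n[2] == last
        ]


def build_forest(tracks: pd.DataFrame, nuclei: pd.DataFrame) -> LineageForest:
    """Assemble a lineage forest from a tracking edge list and nucleus table.

    The edge list has columns ``embryo_id, child_id, parent_id, frame``: the
    child observed at ``frame`` descends from the parent observed at
    ``frame - 1`` (same id = track continuation; a new id = daughter of a
    division).  Every referenced observation must exist in the nucleus table.
    Observations after frame 0 with no incoming edge are orphans: they and
    their descendants are reported in ``orphans`` and excluded from families.
    Cells branching into any number of successors other than 1 or 2 are
    rejected, as is any observation with more than one parent.
    """
    nodes = {
        (r.embryo_id, r.cell_id, r.frame)
        for r in nuclei[["embryo_id", "cell_id", "frame"]].itertuples()
    }
    final_frame = nuclei.groupby("embryo_id")["frame"].max().to_dict()
    parent: dict = {}
    children: dict = {}
    for r in tracks.itertuples():
        child = (r.embryo_id, r.child_id, r.frame)
        par = (r.embryo_id, r.parent_id, r.frame - 1)
        if child not in nodes:
            raise ForestError(f"edge references missing observation {child}")
        if par not in nodes:
            raise ForestError(f"edge references missing observation {par}")
        if child in parent and parent[child] != par:
            raise ForestError(
                f"observation {child} has multiple parents "
                f"({parent[child]} and {par})"
            )
        if child == par:
            raise ForestError(f"self-edge at {child}")
        parent[child] = par
        children.setdefault(par, []).append(child)

    # divisions must produce exactly two daughters
    for par, kids in children.items():
        if len(kids) > 2:
            raise ForestError(
                f"observation {par} has {len(kids)} successors; a division "
                f"has exactly 2"
            )
        if len(kids) == 2 and kids[0][1] == kids[1][1]:
            raise ForestError(f"duplicate daughter ids under {par}")

    founders = sorted(
        (n for n in nodes if n[2] == 0), key=lambda n: (n[0], str(n[1]))
    )
    family_of: dict = {}
    for f in founders:
        stack = [f]
        while stack:
            n = stack.pop()
            if n in family_of:
                raise ForestError(f"cycle or shared node detected at {n}")
            family_of[n] = f
            stack.extend(children.get(n, []))
    orphans = sorted(nodes - set(family_of), key=lambda n: (n[0], n[2],
                                                            str(n[1])))
    return LineageForest(
        nodes=nodes,
        parent=parent,
        children=children,
        founders=founders,
        family_of=family_of,
        final_frame=final_frame,
        orphans=orphans,
    )


def _labels_lookup(labels: pd.DataFrame) -> dict:
    return {
        (r.embryo_id, r.cell_id, r.frame): r.label
        for r in labels.itertuples()
    }


def _normalize_labels(labels: pd.DataFrame) -> pd.DataFrame:
    df = labels.copy()
    if "label" not in df:
        for cand in ("in_out", "true_label"):
            if cand in df:
                df = df.rename(columns={cand: "label"})
                break
    return df[["embryo_id", "cell_id", "frame", "label"]]


def classify_families(
    forest: LineageForest, labels: pd.DataFrame
) -> pd.DataFrame:
    """Fate class per family from frame-0 and final-frame position labels.

    ``labels`` has columns ``embryo_id, cell_id, frame`` and a label column
    (``label``, ``in_out`` or ``true_label``) with values 'inner'/'outer'.
    Returns one row per family with the class, founder label, leaf-label
    multiset and a ``flagged`` column for OTHER/UNCLASSIFIABLE families.
    """
    lut = _labels_lookup(_normalize_labels(labels))
    rows = []
    for founder in forest.founders:
        if founder not in lut:
            raise ValueError(f"unlabeled founder {founder}")
        start = lut[founder]
        leaves = forest.leaves(founder)
        leaf_labels = []
        for n in leaves:
            if n not in lut:
                raise ValueError(f"unlabeled leaf {n}")
            leaf_labels.append(lut[n])
        n_in = sum(1 for l in leaf_labels if l == "inner")
        n_out = len(leaf_labels) - n_in
        if not leaf_labels:
            cls = "UNCLASSIFIABLE"
        elif start == "inner":
            cls = ("IN-ICM" if n_out == 0
                   else "OTHER" if n_in == 0 else "IN-TE+ICM")
        else:
            cls = ("OUT-TE" if n_in == 0
                   else "OTHER" if n_out == 0 else "OUT-TE+ICM")
        rows.append(
            {
                "embryo_id": founder[0],
                "family_id": founder[1],
                "family_class": cls,
                "start_label": start,
                "n_leaves_inner": n_in,
                "n_leaves_outer": n_out,
                "flagged": cls in ("OTHER", "UNCLASSIFIABLE"),
            }
        )
    return pd.DataFrame(rows)


def _family_frame(forest: LineageForest, values: pd.DataFrame,
                  value_col: str) -> pd.DataFrame:
    """Long table (embryo, family, frame, value) over classified nodes."""
    fam = forest.family_of
    df = values[["embryo_id", "cell_id", "frame", value_col]].copy()
    keys = list(zip(df["embryo_id"], df["cell_id"], df["frame"]))
    df["family_id"] = [fam.get(k, (None, None))[1] for k in keys]
    df = df.dropna(subset=["family_id"])
    return df


def family_mean_trajectory(
    forest: LineageForest,
    values: pd.DataFrame,
    value_col: str = "ch1_std",
    classes: pd.DataFrame | None = None,
) -> dict:
    """Per-family intensity time series, grand means and per-class means.

    ``values`` carries one row per (embryo, cell, frame) with the intensity
    column (typically the standardized reporter channel).  Frames where a
    family has no live cells are missing values, never zeros.  Returns a dict
    with ``per_family`` (families x frames), ``family_grand_mean`` and, when
    ``classes`` (output of :func:`classify_families`) is given,
    ``per_class`` (class x frame means over families).
    """
    long = _family_frame(forest, values, value_col)
    per_family = (
        long.groupby(["embryo_id", "family_id", "frame"])[value_col]
        .mean()
        .unstack("frame")
    )
    grand = per_family.mean(axis=1)
    out = {"per_family": per_family, "family_grand_mean": grand}
    if classes is not None:
        cls = classes.set_index(["embryo_id", "family_id"])["family_class"]
        joined = per_family.join(cls, how="left")
        out["per_class"] = joined.groupby("family_class").mean()
        out["family_class"] = cls
    return out


def initial_intensity(
    forest: LineageForest,
    values: pd.DataFrame,
    value_col: str = "ch1_std",
    classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The founder's frame-0 intensity per family (optionally with class)."""
    v = values.set_index(["embryo_id", "cell_id", "frame"])[value_col]
    rows = []
    for founder in forest.founders:
        if founder not in v.index:
            raise ValueError(f"founder {founder} missing at frame 0")
        rows.append(
            {
                "embryo_id": founder[0],
                "family_id": founder[1],
                "initial": float(v.loc[founder]),
            }
        )
    df = pd.DataFrame(rows)
    if classes is not None:
        df = df.merge(
            classes[["embryo_id", "family_id", "family_class"]],
            on=["embryo_id", "family_id"],
            how="left",
        )
    return df


def position_change_summary(
    forest: LineageForest, labels: pd.DataFrame
) -> dict:
    """Fraction of predecessor->successor transitions that flip inner/outer.

    Uses every edge of the forest (track continuations and division edges).
    Movies with a single frame have no transitions; the fractions are NaN.
    Returns overall and per-family fractions plus the transition count.
    """
    lut = _labels_lookup(_normalize_labels(labels))
    per_family: dict = {}
    flips = 0
    total = 0
    for child, par in forest.parent.items():
        if child not in forest.family_of:
            continue
        if child not in lut or par not in lut:
            raise ValueError(f"missing label for transition {par} -> {child}")
        flip = lut[child] != lut[par]
        fam = forest.family_of[child]
        acc = per_family.setdefault(fam, [0, 0])
        acc[0] += flip
        acc[1] += 1
        flips += flip
        total += 1
    fam_frac = pd.Series(
        {
            (f[0], f[1]): (a[0] / a[1] if a[1] else np.nan)
            for f, a in per_family.items()
        },
        dtype=float,
    )
    return {
        "overall_fraction": (flips / total) if total else float("nan"),
        "n_transitions": total,
        "n_flips": flips,
        "per_family_fraction": fam_frac,
    }


def read_trackmate_xml(path, embryo_id: str = "E00") -> pd.DataFrame:
    """Read a Fiji-tracker XML export (spots + edges) as a tracking table.

    Understands the common dialect with ``<Spot ID=... FRAME=...>`` elements
    and ``<Edge SPOT_SOURCE_ID=... SPOT_TARGET_ID=...>`` elements; each edge
    becomes one ``child_id/parent_id/frame`` row in the CSV dialect consumed
    by :func:`build_forest`.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    frame_of = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID") or spot.get("name")
        frame = spot.get("FRAME") or spot.get("frame")
        if sid is None or frame is None:
            raise ValueError("Spot element lacks ID/FRAME attributes")
        frame_of[sid] = int(float(frame))
    rows = []
    for edge in root.iter("Edge"):
        src = edge.get("SPOT_SOURCE_ID")
        tgt = edge.get("SPOT_TARGET_ID")
        if src is None or tgt is None:
            raise ValueError("Edge element lacks SPOT_SOURCE_ID/SPOT_TARGET_ID")
        rows.append(
            {
                "embryo_id": embryo_id,
                "child_id": tgt,
                "parent_id": src,
                "frame": frame_of[tgt],
            }
        )
    return pd.DataFrame(rows, columns=["embryo_id", "child_id", "parent_id",
                                       "frame"])
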