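"""Mid-parent-value (MPV) trajectories: genome merger vs genome doubling.

The in-silico mid-parent value — the average of the two parents'
expression — is the additive expectation for a hybrid.  Comparing MPV,
the diploid F1 hybrid (genome merger only) and the later-generation
allotetraploid F18 (merger followed by genome doubling) partitions every
gene's expression change into four classes:

========================  =================================
MPV = F1 = F18            no change
MPV = F1 != F18           change due to genome doubling
MPV != F1 = F18           change due to genome merger
anything else             other
========================  =================================

The same partition applies to homoeologue-expression-bias states, with
the parental R-C divergence taking the role of the MPV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de_stats import CountMatrix, call_de, rpkm
from .homoeolog import HEB_STATES

__all__ = [
    "compute_mpv",
    "mpv_count_matrix",
    "classify_trajectory",
    "classify_trajectory_table",
    "classify_heb_trajectory",
    "TRAJECTORY_CLASSES",
]

TRAJECTORY_CLASSES = ("no-change", "doubling", "merger", "other")


def compute_mpv(cm: CountMatrix, maternal: str = "R", paternal: str = "C") -> pd.Series:
    """Mid-parent normalised expression per gene.

    Each parent's replicate RPKM values are averaged; the MPV is the mean
    of the two parental averages.
    """
    means = {}
    for parent in (maternal, paternal):
        samples = cm.group_samples(parent)
        vals = np.column_stack(
            [
                rpkm(cm.counts[s].values, cm.lengths.values, cm.library_sizes[s])
                for s in samples
            ]
        )
        means[parent] = vals.mean(axis=1)
    mpv = (means[maternal] + means[paternal]) / 2.0
    return pd.Series(mpv, index=cm.genes, name="mpv")


def mpv_count_matrix(
    cm: CountMatrix, maternal: str = "R", paternal: str = "C"
) -> CountMatrix:
    """Count matrix augmented with an ``MPV`` pseudo-library.

    The Fisher test machinery needs integer counts, so the MPV library is
    built as the halved sum of the pooled parental counts, rounded to the
    nearest integer, with the pooled parental library sizes averaged the
    same way.
    """
    pooled = (
        cm.pooled_counts(maternal).values + cm.pooled_counts(paternal).values
    ) / 2.0
    lib = (
        cm.pooled_library_size(maternal) + cm.pooled_library_size(paternal)
    ) / 2.0
    counts = cm.counts.copy()
    counts["MPV"] = np.rint(pooled).astype(np.int64)
    lib_sizes = pd.concat(
        [cm.library_sizes, pd.Series({"MPV": float(np.rint(lib))})]
    )
    groups = pd.concat([cm.groups, pd.Series({"MPV": "MPV"})])
    return CountMatrix(counts, cm.lengths, lib_sizes, groups)


def classify_trajectory(call_mpv_f1: str, call_mpv_f18: str, call_f1_f18: str) -> str:
    """Trajectory class from the three DE calls (each in up/down/ns).

    ``no-change`` requires all three calls ns; ``doubling`` is
    MPV = F1 (ns) with F1 != F18; ``merger`` is MPV != F1 with F1 = F18;
    every remaining pattern is ``other``.
    """
    for c in (call_mpv_f1, call_mpv_f18, call_f1_f18):
        if c not in ("up", "down", "ns"):
            raise ValueError(f"invalid DE call {c!r}")
    if call_mpv_f1 == call_mpv_f18 == call_f1_f18 == "ns":
        return "no-change"
    if call_mpv_f1 == "ns" and call_f1_f18 != "ns":
        return "doubling"
    if call_mpv_f1 != "ns" and call_f1_f18 == "ns":
        return "merger"
    return "other"


def classify_trajectory_table(
    cm: CountMatrix,
    f1: str = "F1",
    f18: str = "F18",
    maternal: str = "R",
    paternal: str = "C",
) -> pd.DataFrame:
    """Per-gene trajectory classes from a four-group count matrix."""
    aug = mpv_count_matrix(cm, maternal, paternal)
    de_mpv_f1 = call_de(aug, "MPV", f1)
    de_mpv_f18 = call_de(aug, "MPV", f18)
    de_f1_f18 = call_de(aug, f1, f18)
    cls = [
        classify_trajectory(a, b, c)
        for a, b, c in zip(de_mpv_f1["call"], de_mpv_f18["call"], de_f1_f18["call"])
    ]
    return pd.DataFrame(
        {
            "call_mpv_f1": de_mpv_f1["call"],
            "call_mpv_f18": de_mpv_f18["call"],
            "call_f1_f18": de_f1_f18["call"],
            "trajectory": cls,
        },
        index=aug.genes,
    ).rename_axis("gene")


def classify_heb_trajectory(divergence: str, f1_state: str, f18_state: str) -> str:
    """Trajectory class for homoeologue-bias states (R>C / R=C / R<C).

    The parental R-C divergence plays the MPV role: ``no-change`` when all
    three states are equal, ``doubling`` when the divergence survives in F1
    but F18 differs, ``merger`` when F1 departs from the divergence and F18
    matches F1.
    """
    for s in (divergence, f1_state, f18_state):
        if s not in HEB_STATES:
            raise ValueError(f"invalid HEB state {s!r}")
    if divergence == f1_state == f18_state:
        return "no-change"
    if divergence == f1_state and f1_state != f18_state:
        return "doubling"
    if divergence != f1_state and f1_state == f18_state:
        return "merger"
    return "other"
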