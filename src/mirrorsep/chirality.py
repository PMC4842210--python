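"""Orientation statistics and labels for model ensembles.

Three routes to an orientation call are provided:

* ``phi_plus_ratio``   — the fraction of positive phi angles, a cheap
  per-model chirality statistic (right-handed helices have negative phi);
* ``assign_orientation`` — reference-based: superpose against a reference
  structure and against its ideal mirror image, pick the closer one;
* ``separate_ensemble`` — reference-free: split an ensemble in two by a
  1-D score (e.g. the Ramachandran potential) with deterministic 2-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geometry import backbone_dihedrals, ca_rmsd, mirror_reflect
from .structure_io import StructureModel

#: RMSD difference below which a reference-based call is refused
TIE_TOLERANCE = 1e-6


class Orientation(str, Enum):
    PROPER = "proper"
    MIRROR = "mirror"
    AMBIGUOUS = "ambiguous"


@dataclass
class ChiralityStats:
    """The positive-phi ratio and its counts."""

    phi_plus_ratio: float
    n_positive_phi: int
    n_defined_phi: int


def phi_plus_ratio(model: StructureModel) -> ChiralityStats:
    """Fraction of strictly positive phi among defined phi angles.

    phi exactly 0 counts as non-positive ("positive" read strictly).
    """
    phis = backbone_dihedrals(model).defined_phi
    if len(phis) == 0:
        raise ValueError("model has no defined phi angles")
    n_pos = int(np.sum(phis > 0))
    return ChiralityStats(
        phi_plus_ratio=n_pos / len(phis),
        n_positive_phi=n_pos,
        n_defined_phi=len(phis),
    )


@dataclass
class OrientationLabel:
    value: Orientation
    rmsd_to_ref: float
    rmsd_to_mirror_ref: float


def assign_orientation(model: StructureModel,
                       reference: StructureModel) -> OrientationLabel:
    """Label a model by superposition against the reference and its mirror."""
    if len(model) != len(reference):
        raise ValueError(
            f"model has {len(model)} residues, reference {len(reference)}"
        )
    r_ref = ca_rmsd(model, reference)
    r_mir = ca_rmsd(model, mirror_reflect(reference))
    if abs(r_ref - r_mir) < TIE_TOLERANCE:
        value = Orientation.AMBIGUOUS
    elif r_ref < r_mir:
        value = Orientation.PROPER
    else:
        value = Orientation.MIRROR
    return OrientationLabel(value=value, rmsd_to_ref=r_ref,
                            rmsd_to_mirror_ref=r_mir)


def separate_ensemble(scores, handedness: str = "right") -> list[Orientation]:
    """Reference-free two-group split of 1-D per-model scores.

    Deterministic 2-means: centers start at the min and max score and are
    iterated to convergence.  For a right-handed native the lower-score
    cluster is labelled proper; for a left-handed native the interpretation
    flips.
    """
    scores = np.asarray(list(scores), dtype=float)
    if len(scores) < 4:
        raise ValueError("need at least 4 models to separate")
    if handedness not in ("right", "left"):
        raise ValueError(f"handedness must be 'right' or 'left', got {handedness!r}")
    lo, hi = float(scores.min()), float(scores.max())
    if hi - lo == 0:
        raise ValueError("no separation: all scores identical")

    centers = np.array([lo, hi])
    for _ in range(200):
        assign = np.abs(scores[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            scores[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in (0, 1)
        ])
        if np.allclose(new, centers):
            break
        centers = new

    low_is_proper = handedness == "right"
    labels = []
    for a in assign:
        in_low = a == 0
        labels.append(Orientation.PROPER if in_low == low_is_proper
                      else Orientation.MIRROR)
    return labels
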