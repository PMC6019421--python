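"""Response-weighted texture averaging of shape-normalized stimuli.

The image analysis summarizes what the stimulus categories look like — and
what participants *think* they look like — with texture averages: each
contributing image is warped onto a common Procrustes mean shape and the
warped textures are combined as a weighted mean.  Veridical averages weight
by ground truth (unit weights); perceived averages weight each stimulus by
the number of times a participant subgroup classified it with a given
label, regardless of truth.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import AverageImage, Category, LandmarkSet, StimulusImage, TrialRecord
from .warping import PiecewiseAffineWarper, mean_shape

SIX_LABELS = (
    "veridical_mask", "veridical_face",
    "perceived_mask_high", "perceived_face_high",
    "perceived_mask_low", "perceived_face_low",
)


def texture_average(images: Sequence[StimulusImage],
                    weights: Optional[Sequence[float]] = None,
                    label: str = "average",
                    target_shape: Optional[LandmarkSet] = None,
                    warped: Optional[Mapping[str, np.ndarray]] = None,
                    total_responses: Optional[int] = None) -> AverageImage:
    """Weighted texture average of stimuli in mean-shape space.

    Every image is warped to ``target_shape`` (by default the Procrustes
    mean shape of the contributing images themselves) and the output pixel
    is sum(w_i * pixel_i) / sum(w_i).  ``warped`` may supply pre-computed
    warped textures keyed by stimulus id, which the six-averages builder
    uses to avoid re-warping the same image for every average.
    """
    if not images:
        raise ValueError("no images to average")
    if weights is None:
        w = np.ones(len(images))
    else:
        w = np.asarray(weights, dtype=float)
    if w.size != len(images):
        raise ValueError("weights must align with images")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")

    if target_shape is None:
        if len(images) == 1:
            target_shape = images[0].landmarks
        else:
            target_shape, _ = mean_shape([im.landmarks for im in images])
    frame = images[0].shape
    warper: Optional[PiecewiseAffineWarper] = None
    acc = np.zeros(frame, dtype=float)
    for im, wi in zip(images, w):
        if wi == 0.0:
            continue
        if warped is not None and im.id in warped:
            tex = warped[im.id]
        else:
            if warper is None:
                warper = PiecewiseAffineWarper(target_shape, frame)
            tex = warper.warp(im.pixels, im.landmarks)
        acc += wi * tex
    return AverageImage(
        label=label,
        texture=acc / w.sum(),
        shape=target_shape,
        stimulus_ids=tuple(im.id for im in images),
        weights=w,
        total_responses=total_responses,
    )


def perceived_weights(trials: Sequence[TrialRecord],
                      subgroup_participants: Iterable[str],
                      label: str) -> Dict[str, int]:
    """Response counts per stimulus for one perceived average.

    The weight of stimulus ``s`` is the number of trials on which a member
    of the subgroup classified ``s`` with ``label`` ("mask" or "face").
    Stimuli no subgroup member labelled this way are absent from the
    result (zero-weight stimuli are excluded from the average).
    """
    if label not in ("mask", "face"):
        raise ValueError("label must be 'mask' or 'face'")
    members = set(subgroup_participants)
    if not members:
        raise ValueError("empty subgroup")
    counts: Dict[str, int] = {}
    for t in trials:
        if t.participant_id in members and t.response == label:
            counts[t.stimulus_id] = counts.get(t.stimulus_id, 0) + 1
    if not counts:
        raise ValueError(f"no stimulus received label {label!r} from the subgroup")
    return counts


def build_six_averages(stimuli: Sequence[StimulusImage],
                       trials: Sequence[TrialRecord],
                       high_participants: Iterable[str],
                       low_participants: Iterable[str],
                       exclude: Iterable[str] = (),
                       ) -> Dict[str, AverageImage]:
    """The six category averages of the two-category (exp2) image analysis.

    Veridical mask/face averages use truth labels with unit weights; the
    four perceived averages weight stimuli by how often the high- or
    low-performing subgroup classified them "mask" or "face".  Stimuli on
    the exclusion list (e.g. images unfit for landmarking) are dropped
    before anything is computed.  All six averages share one Procrustes
    mean shape, computed from the included stimuli, so difference images
    can be formed between any pair; each image is warped exactly once.
    """
    excluded = set(exclude)
    included = [s for s in stimuli if s.id not in excluded]
    if not included:
        raise ValueError("no stimuli left after exclusions")
    cats = {s.category for s in included}
    if cats - {Category.REAL_FACE, Category.HIGH_REALISM_MASK}:
        raise ValueError("six-average analysis is defined for two-category "
                         "(face / high-realism mask) stimulus sets")
    target, _ = mean_shape([s.landmarks for s in included])
    warper = PiecewiseAffineWarper(target, included[0].shape)
    warped = {s.id: warper.warp(s.pixels, s.landmarks) for s in included}
    trials = [t for t in trials if t.stimulus_id not in excluded]

    masks = [s for s in included if s.truth == "mask"]
    faces = [s for s in included if s.truth == "face"]
    out: Dict[str, AverageImage] = {
        "veridical_mask": texture_average(
            masks, label="veridical_mask", target_shape=target, warped=warped),
        "veridical_face": texture_average(
            faces, label="veridical_face", target_shape=target, warped=warped),
    }
    for grp_name, members in (("high", list(high_participants)),
                              ("low", list(low_participants))):
        for resp in ("mask", "face"):
            counts = perceived_weights(trials, members, resp)
            imgs = [s for s in included if counts.get(s.id, 0) > 0]
            w = [counts[s.id] for s in imgs]
            out[f"perceived_{resp}_{grp_name}"] = texture_average(
                imgs, w, label=f"perceived_{resp}_{grp_name}",
                target_shape=target, warped=warped,
                total_responses=int(sum(w)))
    return out
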