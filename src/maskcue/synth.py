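"""Synthetic stimuli, observers and trials for the mask-detection task.

No public corpus of hyper-realistic-mask photographs or human responses
exists, so the pipeline is exercised on a parametric stand-in with the same
statistical skeleton as the emulated experiments:

* 540 x 385 grayscale face-like stimuli in three categories (real face,
  low-realism mask, high-realism mask), each rendered from a jittered face
  template with consistent landmarks;
* a localized category cue in the band directly under the eyes (masks lose
  local contrast there — no lower lashes — and shift complexion), plus a
  weak global "silicone" cue (mild whole-face contrast flattening and a
  small brightness offset); low-realism masks exaggerate the global cue
  grossly, making them separable from both other classes;
* per-stimulus nuisance variation (complexion level, feature contrast,
  idiosyncratic under-eye texture, geometric jitter, pixel noise) so that
  no cue is deterministic;
* observers that weight standardized cue statistics from 30 horizontal
  image bands — aligned one-to-one with the 30-slice image analysis — add
  internal noise, and threshold the summed evidence at a criterion.

All randomness descends from a single integer seed through named
``numpy.random.SeedSequence`` streams, so identical seeds reproduce
stimuli and trial tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .types import Category, LandmarkSet, ObserverProfile, StimulusImage, TrialRecord

# ---------------------------------------------------------------------------
# Frame geometry.  The canonical analysis crop (300 x 228) and slice count
# (30, i.e. 10-pixel slices) are fixed by the image-correlation protocol;
# the under-eye cue band of the template coincides with slice 15.
# ---------------------------------------------------------------------------

FRAME_HEIGHT = 540
FRAME_WIDTH = 385

#: (top, left, height, width) of the internal-features crop used by both the
#: observers' band statistics and the slice-correlation analysis.
DEFAULT_CROP = (120, 78, 300, 228)

N_BANDS = 30
INFORMATIVE_BAND = 15
#: Fraction of mask stimuli whose fit shows under-eye anomalies.
CARRIER_FRACTION = 0.35  # 1-based, top-down: rows 260..269 of the full frame

_SLICE_H = DEFAULT_CROP[2] // N_BANDS  # 10 px
#: Full-frame row range of the under-eye cue band (slice 15 of the crop).
CUE_ROWS = (
    DEFAULT_CROP[0] + (INFORMATIVE_BAND - 1) * _SLICE_H,
    DEFAULT_CROP[0] + INFORMATIVE_BAND * _SLICE_H,
)

# Template geometry (frame coordinates, row/col).
_HEAD_CENTER = (270.0, 192.5)
_HEAD_AXES = (185.0, 130.0)  # (row semi-axis, col semi-axis)
_EYE_ROW, _EYE_DCOL = 240.0, 52.0
_BROW_ROW = 205.0
_MOUTH_ROW = 365.0


@dataclass(frozen=True)
class CueParams:
    """Parameters of the category cues and of per-stimulus nuisance variation.

    Cue parameters
    --------------
    under_eye_attenuation : float in [0, 1]
        Multiplier on local contrast inside the under-eye band for mask
        stimuli (1 = no cue, 0 = fully flattened).  Each mask draws its own
        value uniformly within ``attenuation_jitter`` of this mean.
    under_eye_offset : float
        Signed intensity shift added inside the under-eye band for masks
        (the mask edge meeting the skin shifts apparent complexion).
    mask_blotch_amplitude : float
        S.d. of mask-specific under-eye anomalies (surface and complexion
        discontinuities where the eye holes meet the wearer's skin) at
        random positions per mask, so the informative band's content is
        idiosyncratic to each mask rather than a fixed template difference.
    mask_contrast_flatten : float
        Whole-face feature-contrast multiplier for high-realism masks
        (silicone mildly flattens fine texture everywhere).
    mask_global_offset : float
        Small whole-face brightness shift for high-realism masks.
    low_realism_flatten, low_realism_offset : float
        The gross global cue of low-realism masks (strong flattening plus a
        brightness shift), which makes them separable in every band.

    Nuisance parameters (apply to every category)
    ---------------------------------------------
    complexion_sd : per-stimulus whole-face brightness s.d. (intensity units).
    contrast_sd : per-stimulus feature-contrast multiplier s.d. (around 1).
    skin_texture_amplitude : s.d. of the fixed fine-grain complexion
        texture shared by all stimuli (attached to the face, flattened by
        masks like every other textural feature).
    texture_amplitude : s.d. of idiosyncratic under-eye texture bumps
        (eyelash raggedness, shadows, skin blotches at random positions).
    noise_sd : i.i.d. Gaussian pixel noise s.d.
    jitter_scale : scale factor on geometric jitter (global similarity
        transform plus small per-feature displacements).
    """

    under_eye_attenuation: float = 0.2
    under_eye_offset: float = 55.0
    attenuation_jitter: float = 0.15
    offset_jitter: float = 3.0
    mask_blotch_amplitude: float = 115.0
    mask_contrast_flatten: float = 0.82
    mask_global_offset: float = 5.5
    low_realism_flatten: float = 0.55
    low_realism_offset: float = 25.0
    complexion_sd: float = 5.0
    contrast_sd: float = 0.10
    skin_texture_amplitude: float = 38.0
    texture_amplitude: float = 90.0
    noise_sd: float = 1.0
    jitter_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.under_eye_attenuation <= 1.0:
            raise ValueError("under_eye_attenuation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")


# ---------------------------------------------------------------------------
# Landmark schema: 60 named points shared by every stimulus.
# ---------------------------------------------------------------------------

def _outline_angles() -> np.ndarray:
    return np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)


LANDMARK_SCHEMA: Tuple[str, ...] = tuple(
    [f"outline_{i}" for i in range(24)]
    + ["brow_l_outer", "brow_l_inner", "brow_r_inner", "brow_r_outer"]
    + [
        "eye_l_outer", "eye_l_inner", "eye_l_top", "eye_l_bottom",
        "eye_r_inner", "eye_r_outer", "eye_r_top", "eye_r_bottom",
    ]
    + ["under_eye_l", "under_eye_r"]
    + ["nose_bridge", "nose_tip", "nostril_l", "nostril_r"]
    + ["mouth_l", "mouth_r", "mouth_top", "mouth_bottom"]
    + ["forehead", "cheek_l", "cheek_r", "chin", "jaw_l", "jaw_r",
       "jawline_l", "jawline_r"]
    + ["band_top_l", "band_top_c", "band_top_r",
       "band_bot_l", "band_bot_c", "band_bot_r"]
)


def _template_landmarks() -> np.ndarray:
    """Landmark template in (x, y) frame coordinates, pre-jitter."""
    cy, cx = _HEAD_CENTER
    ar, ac = _HEAD_AXES
    pts: List[Tuple[float, float]] = []
    for th in _outline_angles():
        pts.append((cx + ac * np.sin(th), cy - ar * np.cos(th)))
    for dx in (-82.0, -22.0, 22.0, 82.0):  # brows
        pts.append((cx + dx, _BROW_ROW))
    for side in (-1.0, 1.0):  # eyes: outer, inner, top, bottom
        ex = cx + side * _EYE_DCOL
        pts.append((ex + side * 20.0, _EYE_ROW))
        pts.append((ex - side * 20.0, _EYE_ROW))
        pts.append((ex, _EYE_ROW - 9.0))
        pts.append((ex, _EYE_ROW + 9.0))
    for side in (-1.0, 1.0):  # under-eye pair, centre of the cue band
        pts.append((cx + side * _EYE_DCOL, float(CUE_ROWS[0] + _SLICE_H / 2)))
    pts.append((cx, 252.0))
    pts.append((cx, 315.0))
    pts.append((cx - 12.0, 318.0))
    pts.append((cx + 12.0, 318.0))
    pts.append((cx - 38.0, _MOUTH_ROW))
    pts.append((cx + 38.0, _MOUTH_ROW))
    pts.append((cx, _MOUTH_ROW - 9.0))
    pts.append((cx, _MOUTH_ROW + 9.0))
    pts.append((cx, 160.0))          # forehead
    pts.append((cx - 80.0, 305.0))   # cheeks
    pts.append((cx + 80.0, 305.0))
    pts.append((cx, 430.0))          # chin
    pts.append((cx - 55.0, 398.0))   # jaw
    pts.append((cx + 55.0, 398.0))
    pts.append((cx - 69.0, 405.0))   # jawline shadow crossings
    pts.append((cx + 69.0, 405.0))
    for row in (float(CUE_ROWS[0]) - 0.5, float(CUE_ROWS[1]) - 0.5):
        for dx in (-52.0, 0.0, 52.0):  # under-eye band edge anchors
            pts.append((cx + dx, row))
    return np.asarray(pts, dtype=float)


_TEMPLATE_POINTS = _template_landmarks()
# Feature group of each landmark, for per-feature jitter.
_FEATURE_OF_POINT = (
    ["head"] * 24
    + ["brow_l"] * 2 + ["brow_r"] * 2
    + ["eye_l"] * 4 + ["eye_r"] * 4
    + ["head", "head"]
    + ["nose"] * 4
    + ["mouth"] * 4
    + ["head"] * 14
)
_FEATURES = ("brow_l", "brow_r", "eye_l", "eye_r", "nose", "mouth")

_GRID_Y, _GRID_X = np.mgrid[0:FRAME_HEIGHT, 0:FRAME_WIDTH].astype(np.float32)


def _make_face_texture() -> np.ndarray:
    """Fixed fine-grain complexion texture of the face template (unit s.d.).

    A band-limited noise pattern, identical for every stimulus and attached
    to the face (sampled in template coordinates), so that the whole-face
    contrast cues leave spatially structured — hence correlatable —
    mask-minus-face differences in every horizontal slice, not only where
    the discrete features sit.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(np.random.SeedSequence([1234567, 7]))
    raw = rng.standard_normal((FRAME_HEIGHT, FRAME_WIDTH))
    smooth = gaussian_filter(raw, sigma=4.0, mode="reflect")
    return (smooth / smooth.std()).astype(np.float32)


_FACE_TEXTURE = _make_face_texture()


def _soft(d: np.ndarray, width: float = 1.2) -> np.ndarray:
    """Soft-edged inside mask for a signed distance-like field d<=0 inside."""
    return np.clip(1.0 - d / width, 0.0, 1.0)


def _ellipse_field(ty: np.ndarray, tx: np.ndarray, cy: float, cx: float,
                   ry: float, rx: float) -> np.ndarray:
    return np.sqrt(((ty - cy) / ry) ** 2 + ((tx - cx) / rx) ** 2) - 1.0


@dataclass(frozen=True)
class _Jitter:
    scale: float
    angle: float
    dy: float
    dx: float
    feature_offsets: Dict[str, Tuple[float, float]]


def _draw_jitter(rng: np.random.Generator, j: float) -> _Jitter:
    scale = float(np.exp(rng.normal(0.0, 0.015 * j)))
    angle = float(rng.normal(0.0, np.deg2rad(1.2) * j))
    dy, dx = rng.normal(0.0, 2.0 * j, size=2)
    offs = {
        f: (float(o[0]), float(o[1]))
        for f, o in zip(_FEATURES, rng.normal(0.0, 1.3 * j, size=(len(_FEATURES), 2)))
    }
    return _Jitter(scale, angle, float(dy), float(dx), offs)


def _render(category: Category, cue: CueParams, rng: np.random.Generator,
            blotch_carrier: Optional[bool] = None
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Render one stimulus; returns (float pixels, landmark (x, y) points).

    All random draws happen unconditionally and in a fixed order, so two
    calls with the same seed but different categories share every nuisance
    draw — a matched mask/face pair differs only by the category cues.
    """
    jit = _draw_jitter(rng, cue.jitter_scale)
    complexion = float(rng.normal(0.0, cue.complexion_sd))
    contrast = float(rng.normal(1.0, cue.contrast_sd))
    # Idiosyncratic under-eye texture: smooth bumps at random positions.
    n_bumps = 8
    bump_amp = rng.normal(0.0, cue.texture_amplitude, size=n_bumps)
    bump_col = rng.uniform(70.0, 315.0, size=n_bumps)
    bump_sig = rng.uniform(10.0, 26.0, size=n_bumps)
    # Mask-specific under-eye anomalies (drawn unconditionally so matched
    # pairs share streams; applied only to mask categories).  Only some
    # masks fit poorly enough around the eyes to show them; those that do
    # show them strongly.
    n_blotch = 6
    carrier_draw = rng.random() < CARRIER_FRACTION  # drawn unconditionally
    carrier = carrier_draw if blotch_carrier is None else bool(blotch_carrier)
    blotch_amp = float(carrier) * rng.normal(
        0.0, cue.mask_blotch_amplitude / np.sqrt(CARRIER_FRACTION), size=n_blotch)
    blotch_col = rng.uniform(70.0, 315.0, size=n_blotch)
    blotch_sig = rng.uniform(25.0, 50.0, size=n_blotch)
    att = float(np.clip(
        cue.under_eye_attenuation + rng.uniform(-1.0, 1.0) * cue.attenuation_jitter,
        0.0, 1.0))
    ue_offset = float(cue.under_eye_offset + rng.normal(0.0, cue.offset_jitter))
    noise = rng.standard_normal((FRAME_HEIGHT, FRAME_WIDTH), dtype=np.float32)

    cy, cx = _HEAD_CENTER
    cos_a, sin_a = np.cos(jit.angle), np.sin(jit.angle)
    # Template coordinates of each frame pixel (inverse similarity).
    yr = _GRID_Y - np.float32(cy + jit.dy)
    xr = _GRID_X - np.float32(cx + jit.dx)
    ty = (np.float32(cos_a) * yr + np.float32(sin_a) * xr) / np.float32(jit.scale) + np.float32(cy)
    tx = (np.float32(-sin_a) * yr + np.float32(cos_a) * xr) / np.float32(jit.scale) + np.float32(cx)

    def tbox(y0: float, y1: float, x0: float, x1: float) -> Tuple[slice, slice]:
        """Image-index window safely containing a template-coordinate box."""
        pad = 35
        return (slice(max(int(y0) - pad, 0), min(int(y1) + pad + 1, FRAME_HEIGHT)),
                slice(max(int(x0) - pad, 0), min(int(x1) + pad + 1, FRAME_WIDTH)))

    head = _ellipse_field(ty, tx, cy, cx, *_HEAD_AXES)
    head_mask = _soft(head * min(_HEAD_AXES), 3.0)
    r2 = ((ty - cy) / _HEAD_AXES[0]) ** 2 + ((tx - cx) / _HEAD_AXES[1]) ** 2
    skin = (170.0 - 45.0 * np.clip(r2, 0.0, 1.0)).astype(np.float32)

    feat = np.zeros_like(skin)  # signed feature layer (deviation from skin)

    def fpos(name: str, row: float, col: float) -> Tuple[float, float]:
        oy, ox = jit.feature_offsets[name]
        return row + oy, col + ox

    for side, name in ((-1.0, "brow_l"), (1.0, "brow_r")):
        br, bc = fpos(name, _BROW_ROW, cx + side * _EYE_DCOL)
        w = tbox(br - 5, br + 5, bc - 31, bc + 31)
        d = _ellipse_field(ty[w], tx[w], br, bc, 4.5, 31.0)
        feat[w] += _soft(d * 4.5, 1.5) * (-95.0)
    for side, name in ((-1.0, "eye_l"), (1.0, "eye_r")):
        er, ec = fpos(name, _EYE_ROW, cx + side * _EYE_DCOL)
        w = tbox(er - 9, CUE_ROWS[1] + 7, ec - 30, ec + 30)
        tyw, txw = ty[w], tx[w]
        d = _ellipse_field(tyw, txw, er, ec, 9.0, 20.0)
        white = _soft(d * 9.0, 1.5)
        feat[w] += white * 58.0
        d_iris = np.sqrt((tyw - er) ** 2 + (txw - ec) ** 2) - 7.5
        feat[w] += _soft(d_iris, 1.2) * (-145.0) * white.clip(0.2, 1.0)
        # Lower-lash / under-eye shadow line, kept clear of the cue band;
        # its row tracks the eye's vertical offset (consistent with the
        # eye landmarks the warp uses).
        lash_r = er + (CUE_ROWS[0] - 10.0 - _EYE_ROW)
        d_lash = _ellipse_field(tyw, txw, lash_r, ec, 2.5, 26.0)
        feat[w] += _soft(d_lash * 2.5, 1.2) * (-38.0)
    nr, nc = fpos("nose", 0.0, 0.0)
    w = tbox(246 + nr, 326 + nr, cx + nc - 25, cx + nc + 25)
    tyw, txw = ty[w], tx[w]
    bridge = _soft(np.abs(txw - (cx + nc)) - 3.0, 1.5) * \
        _soft(np.maximum(252.0 - (tyw - nr), (tyw - nr) - 315.0), 4.0)
    # the bridge skips the under-eye band, whose content stays idiosyncratic
    bridge *= 1.0 - _soft(np.maximum(CUE_ROWS[0] - tyw, tyw - (CUE_ROWS[1] - 1.0)), 0.6)
    feat[w] += bridge * 16.0
    for side in (-1.0, 1.0):
        d = np.sqrt((tyw - (318.0 + nr)) ** 2
                    + (txw - (cx + nc + side * 12.0)) ** 2) - 4.0
        feat[w] += _soft(d, 1.2) * (-70.0)
    mr, mc = fpos("mouth", _MOUTH_ROW, cx)
    w = tbox(mr - 10, mr + 10, mc - 39, mc + 39)
    tyw, txw = ty[w], tx[w]
    d = _ellipse_field(tyw, txw, mr, mc, 9.0, 38.0)
    feat[w] += _soft(d * 9.0, 1.5) * (-72.0)
    d_lip = _ellipse_field(tyw, txw, mr, mc, 2.2, 36.0)
    feat[w] += _soft(d_lip * 2.2, 1.0) * (-25.0)

    # Hairline and jaw shadow arcs along the head boundary: deterministic
    # facial shading that mask material flattens like any other feature.
    ring = np.sqrt(np.clip(r2, 0.0, None)) - 0.90
    arc = np.exp(np.float32(-0.5) * (ring / np.float32(0.05)) ** 2)
    feat += np.float32(-20.0) * arc * _soft(ty - 175.0, 12.0)      # hairline
    feat += np.float32(-18.0) * arc * _soft(370.0 - ty, 12.0)      # jaw

    # Under-eye cue band geometry (template rows).
    band_lo, band_hi = CUE_ROWS
    wb = tbox(band_lo - 3, band_hi + 2, 0, FRAME_WIDTH)
    tyb, txb = ty[wb], tx[wb]
    band_env_b = _soft(np.maximum(band_lo - tyb, tyb - (band_hi - 1.0)), 0.6)
    # Tapered profile for the idiosyncratic fields: zero at the band edges
    # so sub-pixel warp error cannot leak their large amplitudes into the
    # neighbouring slices; the complexion offset keeps the flat profile.
    band_taper = (np.sin(np.clip((tyb - (band_lo - 0.5)) / float(_SLICE_H), 0.0, 1.0)
                         * np.pi) ** 2).astype(np.float32)

    # Fixed fine-grain complexion texture, attached to the face.  It is
    # excluded from the under-eye band so that band's content stays purely
    # idiosyncratic per stimulus: a category average there reflects the
    # categories, not the shared template.
    if cue.skin_texture_amplitude > 0:
        sk = map_coordinates(_FACE_TEXTURE, [ty, tx], order=1, mode="nearest")
        amp = np.float32(cue.skin_texture_amplitude)
        feat += amp * sk
        feat[wb] -= amp * sk[wb] * band_env_b

    # Under-eye idiosyncratic texture (per-stimulus bumps).  The field is
    # centred within the band so it redistributes brightness locally
    # without moving the band's mean intensity.
    band_w = band_env_b * head_mask[wb]
    tex = np.zeros_like(tyb)
    for a, c, s in zip(bump_amp, bump_col, bump_sig):
        tex += np.float32(a) * np.exp(-0.5 * ((txb - np.float32(c)) / np.float32(s)) ** 2)
    tex *= band_taper
    taper_mean = float((band_taper * band_w).sum() / band_w.sum())
    tex -= ((tex * band_w).sum() / band_w.sum() / taper_mean) * band_taper
    feat *= contrast
    feat[wb] += tex * band_env_b

    face = skin + np.float32(complexion) + feat

    # --- category cues ---------------------------------------------------
    if category is not Category.REAL_FACE:
        if category is Category.HIGH_REALISM_MASK:
            flatten = cue.mask_contrast_flatten
            g_offset = cue.mask_global_offset
            if carrier:
                # craftsmanship trade-off: masks that fit poorly around
                # the eyes are otherwise better made, so their global
                # give-aways are weaker
                flatten = 1.0 - (1.0 - flatten) * 0.45
                g_offset = g_offset * 0.45
        else:
            flatten = cue.low_realism_flatten
            g_offset = cue.low_realism_offset
        # Whole-face: flatten feature contrast about the smooth skin layer.
        face = skin + np.float32(complexion) + \
            (face - skin - np.float32(complexion)) * np.float32(flatten) + np.float32(g_offset)
        # Under-eye band: local contrast attenuation plus complexion offset,
        # plus this mask's idiosyncratic eye-hole anomalies.
        band = band_env_b * head_mask[wb]
        local = face[wb] - (skin[wb] + np.float32(complexion + g_offset))
        blotch = np.zeros_like(txb)
        for a, c, sg in zip(blotch_amp, blotch_col, blotch_sig):
            blotch += np.float32(a) * np.exp(
                -0.5 * ((txb - np.float32(c)) / np.float32(sg)) ** 2)
        blotch *= band_taper
        # brightness-neutral within the band (taper-shaped correction)
        tmean = float((band_taper * band).sum() / band.sum())
        blotch -= ((blotch * band).sum() / band.sum() / tmean) * band_taper
        # poorly fitting masks show a stronger complexion discontinuity
        ue_off = ue_offset * (1.5 if carrier else 1.0)
        face[wb] += band * ((np.float32(att) - 1.0) * local
                            + np.float32(ue_off) + blotch)

    img = np.float32(10.0) * (1.0 - head_mask) + face * head_mask
    img += noise * np.float32(cue.noise_sd)
    img = np.clip(np.rint(img, out=img), 0, 255)

    # --- landmarks consistent with the jittered geometry ------------------
    pts = _TEMPLATE_POINTS.copy()  # (x, y)
    for i, f in enumerate(_FEATURE_OF_POINT):
        if f in jit.feature_offsets:
            oy, ox = jit.feature_offsets[f]
            pts[i, 0] += ox
            pts[i, 1] += oy
    rel_y = pts[:, 1] - cy
    rel_x = pts[:, 0] - cx
    out_y = cy + jit.dy + jit.scale * (cos_a * rel_y - sin_a * rel_x)
    out_x = cx + jit.dx + jit.scale * (sin_a * rel_y + cos_a * rel_x)
    lm = np.column_stack([
        np.clip(out_x, 0, FRAME_WIDTH - 1),
        np.clip(out_y, 0, FRAME_HEIGHT - 1),
    ])
    return img, lm


def make_stimulus(category: Category | str, cue_params: CueParams,
                  rng_seed: int, *, stimulus_id: Optional[str] = None,
                  blotch_carrier: Optional[bool] = None) -> StimulusImage:
    """Render one 540 x 385 stimulus of the given category.

    The same ``rng_seed`` with different categories yields a matched pair
    sharing all nuisance variation (jitter, complexion, texture, noise),
    differing only by the category cues.  ``blotch_carrier`` overrides the
    per-stimulus draw of whether a mask shows under-eye anomalies (the
    set generator fixes the carrier fraction exactly).
    """
    category = Category(category)
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 901]))
    pixels, lm = _render(category, cue_params, rng, blotch_carrier=blotch_carrier)
    return StimulusImage(
        id=stimulus_id or f"{category.value}_{rng_seed}",
        category=category,
        pixels=pixels.astype(np.uint8),
        landmarks=LandmarkSet(points=lm, schema=LANDMARK_SCHEMA),
    )


#: Category composition of the two emulated designs.
DESIGNS: Dict[str, Dict[Category, int]] = {
    "exp1": {
        Category.HIGH_REALISM_MASK: 37,
        Category.LOW_REALISM_MASK: 37,
        Category.REAL_FACE: 74,
    },
    "exp2": {
        Category.HIGH_REALISM_MASK: 74,
        Category.REAL_FACE: 74,
    },
}


def make_stimulus_set(design: str, cue_params: CueParams = CueParams(),
                      rng_seed: int = 0) -> List[StimulusImage]:
    """Generate the full stimulus set of a design (exp1 or exp2).

    exp1: 37 high-realism masks, 37 low-realism masks, 74 real faces.
    exp2: 74 high-realism masks, 74 real faces.  50% mask prevalence in both.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {sorted(DESIGNS)}")
    ss = np.random.SeedSequence([int(rng_seed), 101])
    counts = DESIGNS[design]
    total = sum(counts.values())
    child_seeds = (ss.generate_state(total) % (2 ** 31)).astype(np.int64)
    carrier_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 404]))
    out: List[StimulusImage] = []
    k = 0
    for cat, n in counts.items():
        if cat is Category.REAL_FACE:
            carriers = np.zeros(n, dtype=bool)
        else:
            # fix the carrier fraction exactly within each mask category
            carriers = np.zeros(n, dtype=bool)
            n_carrier = int(round(CARRIER_FRACTION * n))
            carriers[carrier_rng.choice(n, size=n_carrier, replace=False)] = True
        for i in range(n):
            out.append(make_stimulus(
                cat, cue_params, int(child_seeds[k]),
                stimulus_id=f"{design}_{cat.value}_{i:03d}",
                blotch_carrier=bool(carriers[i])))
            k += 1
    return out


# ---------------------------------------------------------------------------
# Band cue statistics and the observer decision model.
# ---------------------------------------------------------------------------

def band_statistics(stimuli: Sequence[StimulusImage],
                    crop: Tuple[int, int, int, int] = DEFAULT_CROP,
                    n_bands: int = N_BANDS) -> np.ndarray:
    """Standardized band cue statistics, one row per stimulus.

    For each of ``n_bands`` equal horizontal bands of the analysis crop the
    statistic combines the band's mean intensity (z-scored across the
    stimulus set) and its mean local contrast — mean absolute horizontal
    neighbor difference, a high-pass measure insensitive to smooth shading
    gradients — z-scored and negated, so that mask-typical content
    (brighter complexion, reduced fine-grain contrast) takes positive
    values.  Returns an (n_stimuli, n_bands) array.
    """
    if not stimuli:
        raise ValueError("empty stimulus list")
    top, left, h, w = crop
    if h % n_bands != 0:
        raise ValueError("crop height must be divisible by n_bands")
    bh = h // n_bands
    means = np.empty((len(stimuli), n_bands))
    sds = np.empty((len(stimuli), n_bands))
    for i, s in enumerate(stimuli):
        sub = s.pixels[top:top + h, left:left + w].astype(float)
        means[i] = sub.reshape(n_bands, bh * w).mean(axis=1)
        grad = np.abs(np.diff(sub, axis=1))
        sds[i] = grad.reshape(n_bands, bh * (w - 1)).mean(axis=1)

    def _z(a: np.ndarray) -> np.ndarray:
        mu = a.mean(axis=0)
        sd = a.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (a - mu) / sd

    # Intensity-weighted composite: complexion shifts are the more stable
    # per-stimulus cue; local contrast adds the flattening signal.
    w_int, w_con = 0.8, 0.2
    return (w_int * _z(means) - w_con * _z(sds)) / np.hypot(w_int, w_con)


def default_panel(n_observers: int = 30, rng_seed: int = 0,
                  n_bands: int = N_BANDS,
                  informative_band: int = INFORMATIVE_BAND) -> List[ObserverProfile]:
    """The documented default panel of simulated participants.

    Ability varies monotonically across the panel: observer ``i`` places
    weight ``w_i`` on the informative (under-eye) band, rising from 0 (the
    band is ignored entirely) to 0.95, with the remainder spread uniformly
    over the other bands.  Internal noise falls and the decision criterion
    relaxes with ability, producing expected high-realism-mask accuracies
    from below 50% (conservative, cue-blind observers) to above 85%
    (near-ideal observers) — the near-floor-to-near-ceiling spread the
    individual-differences analyses need.  Prior-knowledge ratings are
    drawn independently of ability (low mean, as in a naive panel).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 202]))
    panel: List[ObserverProfile] = []
    blind = max(n_observers // 3 - 1, 0)  # bottom third ignores the band
    for i in range(n_observers):
        frac = i / max(n_observers - 1, 1)
        w_info = 0.95 * (max(i - blind, 0) / max(n_observers - 1 - blind, 1)) ** 1.1
        w = np.full(n_bands, (1.0 - w_info) / (n_bands - 1))
        w[informative_band - 1] = w_info
        pk = int(np.clip(np.rint(rng.normal(2.7, 1.0)), 1, 7))
        panel.append(ObserverProfile(
            id=f"P{i + 1:02d}",
            band_weights=w,
            internal_noise_sd=1.5 - 1.45 * frac,
            criterion=0.55 - 0.55 * frac,
            lapse_rate=0.10 - 0.09 * frac,
            prior_knowledge=pk,
        ))
    return panel


def simulate_trials(stimuli: Sequence[StimulusImage],
                    observers: Sequence[ObserverProfile],
                    rng_seed: int = 0,
                    crop: Tuple[int, int, int, int] = DEFAULT_CROP,
                    with_rt: bool = True) -> List[TrialRecord]:
    """Simulate every observer categorizing every stimulus once.

    Each observer sees the full stimulus set in an independently shuffled
    order.  Decision evidence is ``D = sum_k w_k s_k + eps`` with ``s_k``
    the standardized band statistics of :func:`band_statistics` and ``eps``
    zero-mean Gaussian internal noise; the response is "mask" iff D exceeds
    the observer's criterion, except that with probability ``lapse_rate``
    the response is replaced by a fair coin flip.  Reaction times are
    log-normal with a median that decreases monotonically in the evidence
    margin ``|D - criterion|`` (hard, near-threshold decisions are slow).
    """
    if not stimuli:
        raise ValueError("empty stimulus list")
    if not observers:
        raise ValueError("empty observer list")
    schema = stimuli[0].landmarks.schema
    for s in stimuli:
        if s.landmarks.schema != schema:
            raise ValueError(f"landmark schema mismatch at stimulus {s.id}")
    n_bands = observers[0].band_weights.size
    stats = band_statistics(stimuli, crop=crop, n_bands=n_bands)
    truths = np.array([s.truth for s in stimuli])
    ids = [s.id for s in stimuli]
    cats = [s.category for s in stimuli]

    records: List[TrialRecord] = []
    for oi, obs in enumerate(observers):
        if obs.band_weights.size != n_bands:
            raise ValueError("observers disagree on band count")
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 303, oi]))
        order = rng.permutation(len(stimuli))
        d = stats @ obs.band_weights + rng.normal(0.0, obs.internal_noise_sd,
                                                  size=len(stimuli))
        resp_mask = d > obs.criterion
        lapse = rng.random(len(stimuli)) < obs.lapse_rate
        coin = rng.random(len(stimuli)) < 0.5
        resp_mask = np.where(lapse, coin, resp_mask)
        if with_rt:
            margin = np.abs(d - obs.criterion)
            median = 600.0 + 1400.0 * np.exp(-1.2 * margin)
            rt = np.exp(np.log(median) + rng.normal(0.0, 0.25, size=len(stimuli)))
        for j in order:
            records.append(TrialRecord(
                participant_id=obs.id,
                stimulus_id=ids[j],
                condition=cats[j],
                truth=str(truths[j]),
                response="mask" if resp_mask[j] else "face",
                rt_ms=float(rt[j]) if with_rt else None,
            ))
    return records


def rt_median_model(margin: np.ndarray | float) -> np.ndarray | float:
    """Analytic median of the RT model as a function of evidence margin."""
    return 600.0 + 1400.0 * np.exp(-1.2 * np.asarray(margin, dtype=float))
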