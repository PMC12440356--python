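"""Per-thymocyte IL-7 and Notch signal-transduction dynamics, with lesions.

IL-7 pathway activity sigma of a wild-type cell relaxes toward the product
of its receptor level, the mean extracellular IL-7 in its microenvironment
and the activation rate a (per hour), and decays at rate d:

    d(sigma)/dt = [IL7R] * <IL7_ex> * a - d * sigma

A dominant-active receptor decouples the drive from both ligand and a:

    d(sigma)/dt = [IL7R] - d * sigma

Notch activity is contact-driven: it rises toward its maximum (1) while the
cell touches any Dll4+ TEC sphere and decays otherwise; the dominant-active
Notch lesion pins it at the maximum. Both linear ODEs are integrated exactly
per agent step (piecewise-constant drive), which is unconditionally stable.

For the proliferation gate the two activities are normalized to their
wild-type maxima and summed. The IL-7 normalization constant is the
steady-state activity of a receptor-saturated wild-type cell sitting at the
reference peak cortical concentration under reference rates; it is a fixed
model constant, so scan scenarios that raise a or lower d genuinely raise
the normalized signal (capped at the pathway maximum of 1).
"""

from __future__ import annotations

import numpy as np

from .params import LesionSpec

# Reference signaling rates fixing the normalization scale (per hour).
NORM_ACTIVATION = 240.0
NORM_DEACTIVATION = 50.0

# Lesion bit flags carried per cell and inherited clonally.
LESION_BITS = {
    "IL7R_WT": 1,
    "IL7R_DA": 2,
    "IL7R_HI": 4,
    "IL7_AUTOCRINE": 8,
    "NOTCH1_DA": 16,
    "DELAYED_DIFF": 32,
    "SLOW_SPEED": 64,
}


def lesion_flags(lesion: LesionSpec | None) -> int:
    """Pack a lesion spec into the per-cell bitmask."""
    if lesion is None:
        return 0
    bits = 0
    for kind in lesion.kinds:
        bits |= LESION_BITS[kind]
    return bits


def il7_normalization(reference_peak: float) -> float:
    """Wild-type steady-state maximum of sigma_IL-7.

    A cell with receptor level 1 held at the reference peak cortical
    concentration reaches sigma* = peak * a_ref / d_ref.
    """
    return reference_peak * NORM_ACTIVATION / NORM_DEACTIVATION


def update_il7_signal(
    sigma: np.ndarray,
    il7r_level: np.ndarray,
    local_il7: np.ndarray,
    activation_rate: float,
    deactivation_rate: float,
    dt_hr: float,
    da_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exact exponential update of sigma_IL-7 over one agent step.

    Wild-type (and receptor-overexpressing) cells are driven by
    ``il7r * local_il7 * a``; dominant-active cells by ``il7r`` alone, so
    their trajectories are invariant under any change to the IL-7 field or
    to the activation rate.
    """
    drive = il7r_level * local_il7 * activation_rate
    if da_mask is not None and np.any(da_mask):
        drive = np.where(da_mask, il7r_level, drive)
    d = deactivation_rate
    if d <= 0.0:
        return sigma + drive * dt_hr
    decay = np.exp(-d * dt_hr)
    return sigma * decay + (drive / d) * (1.0 - decay)


def update_notch_signal(
    sigma: np.ndarray,
    contact: np.ndarray,
    on_rate: float,
    off_rate: float,
    dt_hr: float,
    pinned_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Two-state contact relaxation of Notch activity in [0, 1].

    In contact: sigma -> 1 at rate ``on_rate``; out of contact: exponential
    decay at ``off_rate``. ``pinned_mask`` (dominant-active Notch) forces the
    wild-type maximum regardless of contact.
    """
    rise = np.exp(-on_rate * dt_hr)
    fall = np.exp(-off_rate * dt_hr)
    out = np.where(contact, 1.0 + (sigma - 1.0) * rise, sigma * fall)
    if pinned_mask is not None and np.any(pinned_mask):
        out = np.where(pinned_mask, 1.0, out)
    return out


def combined_proliferative_signal(
    sigma_il7: np.ndarray,
    sigma_notch: np.ndarray,
    il7_norm: float,
) -> np.ndarray:
    """Sum of pathway activities, each normalized to its wild-type maximum
    and capped there; compared against theta_prol for G1 commitment."""
    il7_hat = np.minimum(np.asarray(sigma_il7) / il7_norm, 1.0)
    notch_hat = np.minimum(np.asarray(sigma_notch), 1.0)
    return il7_hat + notch_hat


def lesioned_il7r_level(
    lesion: LesionSpec, rng: np.random.Generator
) -> float:
    """Receptor level assigned to a lesioned founder.

    IL7R_WT and IL7R_DA pin the level at the wild-type maximum of 1;
    IL7R_HI at the overexpression level (10 by default); other lesions keep
    the random uniform wild-type draw.
    """
    if "IL7R_HI" in lesion.kinds:
        return float(lesion.il7r_hi_level)
    if "IL7R_DA" in lesion.kinds or "IL7R_WT" in lesion.kinds:
        return 1.0
    return float(rng.uniform(0.0, 1.0))


def speed_scale(flags: int) -> float:
    return 0.5 if flags & LESION_BITS["SLOW_SPEED"] else 1.0


def diff_rate_scale(flags: int) -> float:
    return 0.5 if flags & LESION_BITS["DELAYED_DIFF"] else 1.0
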