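"""Semi-analytic predictions of the information transmission rate.

The slot channel is approximated as a binary asymmetric (Z-like) channel:
a sent front is extinguished with probability ``p`` (propagation failure,
or annihilation by a backward front spawned by the preceding front), and
the mutual information follows from the 2x2 confusion matrix.  Successive
refinements account for front interaction at finite inter-slot intervals
(event probabilities averaged over the geometric distribution of the
distance to the previous front, with the collision fraction ``gamma``) and
for slot misassignment caused by transit-time dispersion.
"""

from __future__ import annotations

from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.special import erf

from .event_stats import RateModel

__all__ = [
    "extinction_probability_distant",
    "confusion_matrix_extinction",
    "mutual_information_from_matrix",
    "mi_from_extinction",
    "geometric_interval_average",
    "collision_fraction",
    "extinction_probability_interacting",
    "timing_corrected_bitrate",
    "predict_bitrate_curve",
]

K_MAX_DEFAULT = 200


def extinction_probability_distant(
    m: RateModel,
    width: int,
    length: int,
    n_backward: float = 1.285,
    gamma: float = 1.0,
) -> float:
    """Per-slot front extinction probability in the distant-front regime.

    ``p = 1 - exp(-L (lambda_fail + gamma lambda_spawn n_backward))``: a
    front is lost if it fails anywhere along the channel or if its
    predecessor spawned a backward front (``n_backward`` expected per event)
    that collides with it (probability ``gamma``).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if n_backward < 0:
        raise ValueError("n_backward must be >= 0")
    rate = float(m.lambda_fail(width)) + gamma * float(m.lambda_spawn(width)) * n_backward
    return 1.0 - np.exp(-length * rate)


def confusion_matrix_extinction(p: float, q: float = 0.5) -> np.ndarray:
    """Joint (sent, received) probabilities for pure extinction.

    Rows are sent symbols, columns received: a sent 0 is always received as
    0; a sent 1 is erased with probability ``p``.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("p and q must be probabilities")
    return np.array([[1.0 - q, 0.0], [q * p, q * (1.0 - p)]])


def mutual_information_from_matrix(c: np.ndarray) -> float:
    """MI (bits) of a joint probability matrix, with 0 log 0 = 0."""
    c = np.asarray(c, float)
    if np.any(c < -1e-12) or abs(c.sum() - 1.0) > 1e-9:
        raise ValueError("matrix entries must be probabilities summing to 1")
    c = np.clip(c, 0.0, None)
    rows = c.sum(axis=1, keepdims=True)
    cols = c.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = c * (np.log2(c) - np.log2(rows) - np.log2(cols))
    return float(np.nansum(terms))


def mi_from_extinction(p: float, q: float = 0.5) -> float:
    """MI per slot (bits) of the extinction-only channel.

    For ``q = 1/2`` this equals the closed form
    ``1 - [(p+1) log2(p+1) - p log2 p] / 2``.
    """
    return mutual_information_from_matrix(confusion_matrix_extinction(p, q))


def geometric_interval_average(
    p_event_curve: Callable[[float], float],
    q: float,
    t_slot: float,
    k_max: int = K_MAX_DEFAULT,
) -> float:
    """Average an interval-dependent event probability over slot gaps.

    The distance to the previous front is ``k T_slot`` with probability
    ``q (1-q)**(k-1)``; the sum is truncated at ``k_max`` and the remaining
    geometric mass is assigned the curve value at ``k_max T_slot``.
    """
    if q <= 0.0 or q > 1.0:
        raise ValueError("q must be in (0, 1]")
    total = 0.0
    weight = 0.0
    for k in range(1, k_max + 1):
        w = q * (1.0 - q) ** (k - 1)
        total += w * p_event_curve(k * t_slot)
        weight += w
    total += (1.0 - weight) * p_event_curve(k_max * t_slot)
    return total


def collision_fraction(
    v_inv: float,
    t_slot: float,
    length: int,
    q: float = 0.5,
    k_max: int = K_MAX_DEFAULT,
) -> float:
    """Probability that a spawned backward front meets the next front.

    A backward front spawned by a front that is ``k`` slots ahead of the
    next one escapes through the channel start if the gap exceeds twice the
    remaining travel; each term is ``max(0, 1 - k v T_slot / (2 L))``
    weighted geometrically.
    """
    if v_inv <= 0:
        raise ValueError("v_inv must be positive")
    v = 1.0 / v_inv
    total = 0.0
    for k in range(1, k_max + 1):
        frac = 1.0 - k * v * t_slot / (2.0 * length)
        if frac <= 0.0:
            break
        total += q * (1.0 - q) ** (k - 1) * frac
    return total


def extinction_probability_interacting(
    p_fail_avg: float,
    p_spawn_avg: float,
    gamma: float,
    n_backward: float = 1.285,
) -> float:
    """Front elimination probability with interaction corrections.

    Product form ``1 - (1 - p_fail)(1 - gamma p_spawn n_backward)``, equal
    to ``p_fail + gamma p_spawn n_backward`` to first order and clamped to
    [0, 1].
    """
    for name, val in (("p_fail_avg", p_fail_avg), ("p_spawn_avg", p_spawn_avg), ("gamma", gamma)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    p = 1.0 - (1.0 - p_fail_avg) * (1.0 - np.clip(gamma * p_spawn_avg * n_backward, 0.0, 1.0))
    return float(np.clip(p, 0.0, 1.0))


def timing_corrected_bitrate(
    p: float,
    q: float,
    t_slot: float,
    sigma0_sq: float,
    length: int,
) -> tuple[float, float]:
    """MI per slot and bitrate with the transit-time dispersion correction.

    The transit time is taken Gaussian with variance ``sigma0_sq * L``; a
    front is decoded into the correct slot with probability
    ``p_accurate = erf(T_slot / (2 sqrt(2) sigma0 sqrt(L)))``.  Misassigned
    fronts both erase their own slot (``p' = p + (1-p)(1-p_accurate)``) and
    may fake a front in an empty neighboring slot (``p_fake``).  Returns
    ``(MI_slot bits, r bits/h)``.
    """
    if sigma0_sq < 0:
        raise ValueError("sigma0_sq must be >= 0")
    if sigma0_sq == 0.0:
        p_accurate = 1.0
    else:
        p_accurate = float(erf(t_slot / (2.0 * np.sqrt(2.0 * sigma0_sq * length))))
    miss = (1.0 - p) * (1.0 - p_accurate)
    p_prime = np.clip(p + miss, 0.0, 1.0)
    p_fake = np.clip(q * miss - 0.25 * q**2 * miss**2, 0.0, 1.0)
    c = np.array([
        [(1.0 - q) * (1.0 - p_fake), (1.0 - q) * p_fake],
        [q * p_prime * (1.0 - p_fake), q * (1.0 - p_prime) + q * p_prime * p_fake],
    ])
    mi = mutual_information_from_matrix(c)
    return mi, 60.0 * mi / t_slot


def predict_bitrate_curve(
    t_slot_grid,
    length: int,
    width: int,
    level: Literal["distant", "interacting", "interacting+timing"] = "distant",
    rate_model: RateModel | None = None,
    p_fail_curve: Callable[[float], float] | None = None,
    p_spawn_curve: Callable[[float], float] | None = None,
    v_inv: float | None = None,
    sigma0_sq: float | None = None,
    q: float = 0.5,
    n_backward: float = 1.285,
    gamma_distant: float = 1.0,
    k_max: int = K_MAX_DEFAULT,
) -> pd.DataFrame:
    """Predicted bitrate vs inter-slot interval at a chosen correction level.

    - ``distant``: extinction probability from the single-front rate laws
      with a fixed collision probability ``gamma_distant``.
    - ``interacting``: per-interval event probabilities (measured on
      two-front simulations for this channel length) averaged over the
      geometric slot-gap distribution, with ``gamma`` from the transit
      geometry (requires ``v_inv``).
    - ``interacting+timing``: additionally corrects for slot misassignment
      (requires ``sigma0_sq``).
    """
    level_names = ("distant", "interacting", "interacting+timing")
    if level not in level_names:
        raise ValueError(f"level must be one of {level_names}")
    rows = []
    for t_slot in t_slot_grid:
        if level == "distant":
            if rate_model is None:
                raise ValueError("distant level needs a RateModel")
            p = extinction_probability_distant(
                rate_model, width, length, n_backward=n_backward, gamma=gamma_distant
            )
        else:
            if p_fail_curve is None or p_spawn_curve is None or v_inv is None:
                raise ValueError(
                    "interacting levels need p_fail_curve, p_spawn_curve and v_inv "
                    f"measured for L={length}"
                )
            pf = geometric_interval_average(p_fail_curve, q, t_slot, k_max)
            ps = geometric_interval_average(p_spawn_curve, q, t_slot, k_max)
            gam = collision_fraction(v_inv, t_slot, length, q, k_max)
            p = extinction_probability_interacting(pf, ps, gam, n_backward)
        if level == "interacting+timing":
            if sigma0_sq is None:
                raise ValueError("timing correction needs sigma0_sq")
            mi, r = timing_corrected_bitrate(p, q, t_slot, sigma0_sq, length)
        else:
            mi = mi_from_extinction(p, q)
            r = 60.0 * mi / t_slot
        rows.append({
            "T_slot_min": t_slot, "p_extinction": p,
            "MI_slot_bits": mi, "bitrate_bits_per_h": r, "level": level,
        })
    return pd.DataFrame(rows)
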