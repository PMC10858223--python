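"""Session-level association between gamma power change and synchrony
change: assemble per-session post-minus-pre deltas and rank-correlate
them across sessions."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, InvalidInputError

__all__ = ["SessionDelta", "session_deltas", "rank_correlation"]

_REQUIRED = ("gamma_amplitude", "ccg_integral", "popevent_rate")


@dataclass
class SessionDelta:
    session_id: str
    d_gamma: float  # dB, post - pre
    d_ccg_integral: float  # post - pre mean peak integral
    d_popevent_rate: float  # events/s, post - pre


def session_deltas(session_id: str, pre: dict, post: dict) -> SessionDelta:
    """Post-minus-pre deltas for one session.

    ``pre``/``post`` each carry ``gamma_amplitude`` (mean band amplitude,
    a.u.), ``ccg_integral`` (mean CCG peak integral), and
    ``popevent_rate`` (events/s). The gamma delta is expressed in dB.
    """
    for stage in _REQUIRED:
        for name, d in (("pre", pre), ("post", post)):
            if stage not in d:
                raise ConfigurationError(f"missing {stage!r} in {name} results")
    if pre["gamma_amplitude"] <= 0:
        raise InvalidInputError("non-positive pre gamma amplitude")
    return SessionDelta(
        session_id=session_id,
        d_gamma=20.0 * np.log10(post["gamma_amplitude"] / pre["gamma_amplitude"]),
        d_ccg_integral=post["ccg_integral"] - pre["ccg_integral"],
        d_popevent_rate=post["popevent_rate"] - pre["popevent_rate"],
    )


def rank_correlation(
    deltas: list, x: str, y: str
) -> tuple[float, float]:
    """Spearman rho between two delta fields across sessions, with the
    Student-t significance test; ties get average ranks."""
    if len(deltas) < 4:
        raise InsufficientDataError("need >= 4 sessions for a rank correlation")
    xv = np.array([getattr(d, x) for d in deltas], dtype=float)
    yv = np.array([getattr(d, y) for d in deltas], dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise InvalidInputError("constant delta values: correlation undefined")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)
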