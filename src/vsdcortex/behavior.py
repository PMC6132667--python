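"""Conditioned-freezing quantification and tone discrimination.

After auditory Pavlovian conditioning (10 kHz tone paired with a foot
shock, 2.5 kHz neutral), freezing — the fraction of scored time the animal
is immobile apart from respiration — is the behavioral read-out.  An animal
that discriminates freezes to the conditioned tone but not the neutral one;
discrimination is operationalized as the paired within-condition frequency
contrast (the within-subject effect of the repeated-measures ANOVA, which
with two tones equals the paired t-test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError
from .presets import TONES
from .simulate import BehaviorSession


@dataclass
class DiscriminationSummary:
    condition: str
    n_animals: int
    mean_freezing: dict        # {tone: (mean %, sem %)}
    paired_delta: float        # mean (10 kHz - 2.5 kHz) per animal
    F: float
    p: float
    discriminates: bool | None  # None when undecidable (single animal)
    flagged: bool = False


def freezing_percent(immobility, scored_window=None) -> float:
    """Percent of scored samples immobile, from a binary series (10 Hz)."""
    x = np.asarray(immobility)
    if scored_window is not None:
        x = x[scored_window[0]:scored_window[1]]
    if x.size == 0:
        raise InvalidParameterError("empty scored window")
    if not np.isin(x, (0, 1)).all():
        raise InvalidParameterError("immobility series must be binary")
    return 100.0 * float(x.sum()) / x.size


def sessions_frame(sessions) -> pd.DataFrame:
    """Tidy table from BehaviorSession records."""
    return pd.DataFrame([{
        "animal_id": s.animal_id, "condition": s.condition,
        "tone": s.tone, "freezing_percent": s.freezing_percent,
    } for s in sessions])


def discrimination_summary(sessions, condition: str,
                           alpha: float = 0.05) -> DiscriminationSummary:
    """Per-tone freezing summary and the paired CS+ vs CS- contrast.

    Every animal must contribute both tones.  With a single animal the SEM
    and the contrast are undefined; the summary is flagged and
    ``discriminates`` is None.
    """
    df = sessions if isinstance(sessions, pd.DataFrame) else sessions_frame(sessions)
    df = df[df["condition"] == condition]
    if df.empty:
        raise InvalidParameterError(f"no sessions for condition {condition!r}")
    wide = df.pivot_table(index="animal_id", columns="tone",
                          values="freezing_percent")
    for tone in TONES:
        if tone not in wide.columns or wide[tone].isna().any():
            raise InvalidParameterError(
                f"every animal needs a {tone} session for condition {condition!r}")
    n = len(wide)
    means = {}
    for tone in TONES:
        vals = wide[tone].to_numpy(dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
        means[tone] = (float(vals.mean()), float(sem))
    delta = wide[TONES[1]].to_numpy() - wide[TONES[0]].to_numpy()
    if n < 2:
        return DiscriminationSummary(condition, n, means, float(delta.mean()),
                                     float("nan"), float("nan"),
                                     discriminates=None, flagged=True)
    sd = delta.std(ddof=1)
    if sd == 0:
        # identical deltas: no within-animal variability
        F = float("inf") if delta.mean() != 0 else 0.0
        p = 0.0 if delta.mean() != 0 else 1.0
        flagged = True
    else:
        t = delta.mean() / (sd / np.sqrt(n))
        F = float(t ** 2)
        p = float(sps.f.sf(F, 1, n - 1))
        flagged = False
    return DiscriminationSummary(condition, n, means, float(delta.mean()),
                                 F, p, discriminates=bool(p < alpha),
                                 flagged=flagged)
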