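"""Synthetic cohorts, synthetic recordings and the deterministic fixture.

The study's recordings were never deposited, so this module supplies three
replacements:

* :func:`simulate_cohort` — stochastic cohorts whose outcome structure
  (participant/bolus prevalences, per-bolus display behaviour, silent
  aspiration, stopping-rule truncation) is calibrated to the published
  cohort description;
* :func:`simulate_recording` — dual-axis accelerometry with ground-truth
  swallow-burst annotations and a tunable class-conditional effect, so the
  segmentation/feature/classifier chain can be tested end to end;
* :func:`make_table2_fixture` — an exact integer reconstruction of the
  published prevalence table and detection-curve structure (not a sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import (
    BolusTrial,
    CohortDataset,
    Consistency,
    DataError,
    PROTOCOL_BOLUSES,
    Recording,
    VfssRating,
)
from .vfss import apply_stopping_rules

__all__ = [
    "CohortSimParams",
    "SignalSimParams",
    "simulate_cohort",
    "simulate_recording",
    "make_table2_fixture",
    "TABLE2_EXPECTED",
    "CUMULATIVE_EXPECTED",
]

# Published participant-level impairment prevalences (fractions).
_DEFAULT_PREVALENCE = {
    (Consistency.thin, "safety"): 0.230,
    (Consistency.thin, "efficiency"): 0.197,
    (Consistency.mildly_thick, "safety"): 0.139,
    (Consistency.mildly_thick, "efficiency"): 0.179,
    (Consistency.moderately_thick, "safety"): 0.050,
    (Consistency.moderately_thick, "efficiency"): 0.182,
    (Consistency.extremely_thick, "safety"): 0.037,
    (Consistency.extremely_thick, "efficiency"): 0.179,
}

# Cumulative fraction of impaired participants first displaying the thin
# safety problem by bolus k, back-computed from the published detection
# curve (20/40/49/59/62/68 of 68 complete-series impaired participants).
_THIN_SAFETY_CUMULATIVE_DISPLAY = (
    20 / 68,
    40 / 68,
    49 / 68,
    59 / 68,
    62 / 68,
    1.0,
)

# Fraction of safety-impaired participants who are silent aspirators.
_DEFAULT_SILENT_FRACTION = {
    Consistency.thin: 23 / 70,
    Consistency.mildly_thick: 16 / 42,
    Consistency.moderately_thick: 2 / 14,
    Consistency.extremely_thick: 1 / 10,
}


@dataclass
class CohortSimParams:
    n_participants: int = 305
    prevalence: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    thin_safety_cumulative_display: tuple = _THIN_SAFETY_CUMULATIVE_DISPLAY
    display_rate: float = 0.30
    silent_fraction: dict = field(
        default_factory=lambda: dict(_DEFAULT_SILENT_FRACTION)
    )
    not_rateable_rate: float = 0.0
    apply_stopping: bool = True
    seed: int = 0

    def __post_init__(self):
        for k, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise DataError(f"prevalence {k} out of [0, 1]: {p}")
        cum = self.thin_safety_cumulative_display
        if any(b < a for a, b in zip(cum, cum[1:])) or not (
            0.0 <= cum[0] and cum[-1] <= 1.0
        ):
            raise DataError("cumulative display fractions must be non-decreasing in [0, 1]")
        if not (0.0 < self.display_rate <= 1.0):
            raise DataError("display_rate must be in (0, 1]")

    def hazards(self) -> list[float]:
        """Per-bolus conditional first-display probabilities for thin safety."""
        cum = self.thin_safety_cumulative_display
        out, prev = [], 0.0
        for c in cum:
            remaining = 1.0 - prev
            out.append((c - prev) / remaining if remaining > 0 else 1.0)
            prev = c
        return out


def _display_pattern(
    n: int, rng: np.random.Generator, hazards: Optional[Sequence[float]], rate: float
) -> np.ndarray:
    """Which of n boluses display the impairment (at least one does)."""
    shown = np.zeros(n, dtype=bool)
    if hazards is not None:
        first = n - 1
        for k in range(n):
            h = hazards[k] if k < len(hazards) else 1.0
            if rng.random() < h:
                first = k
                break
        shown[first] = True
        shown[first + 1 :] = rng.random(n - first - 1) < rate
    else:
        shown = rng.random(n) < rate
        if not shown.any():
            shown[int(rng.integers(n))] = True
    return shown


def simulate_cohort(params: CohortSimParams) -> CohortDataset:
    """Draw a cohort of ratings (no recordings) from the outcome model.

    Participants carry independent latent impairment per consistency and
    outcome.  Impaired-safety boluses receive PAS 3-7 (8 for silent
    aspirators), safe boluses PAS 1-2; inefficient boluses get a residue
    fill >= 50%, efficient ones < 50% with mass near zero.  Ratings may be
    masked not-rateable at ``not_rateable_rate`` and the administered
    sequence is truncated by the protocol stopping rules.
    """
    rng = np.random.default_rng(params.seed)
    trials: list[BolusTrial] = []
    width = len(str(params.n_participants))
    for i in range(params.n_participants):
        pid = f"S{i + 1:0{width}d}"
        person: list[BolusTrial] = []
        silent: dict[Consistency, bool] = {}
        for consistency in Consistency:
            n = PROTOCOL_BOLUSES[consistency]
            saf_imp = rng.random() < params.prevalence.get((consistency, "safety"), 0.0)
            eff_imp = rng.random() < params.prevalence.get((consistency, "efficiency"), 0.0)
            silent[consistency] = saf_imp and (
                rng.random() < params.silent_fraction.get(consistency, 0.0)
            )
            hazards = (
                params.hazards() if consistency == Consistency.thin else None
            )
            saf_shown = (
                _display_pattern(n, rng, hazards, params.display_rate)
                if saf_imp
                else np.zeros(n, dtype=bool)
            )
            eff_shown = (
                _display_pattern(n, rng, None, params.display_rate)
                if eff_imp
                else np.zeros(n, dtype=bool)
            )
            first_shown = int(np.argmax(saf_shown)) if saf_shown.any() else -1
            for b in range(n):
                if saf_shown[b]:
                    if silent[consistency] and b == first_shown:
                        pas = 8
                    else:
                        pas = int(rng.integers(3, 8))
                else:
                    pas = int(rng.integers(1, 3))
                if eff_shown[b]:
                    vall = float(rng.uniform(50.0, 100.0))
                    pyr = float(rng.uniform(0.0, 50.0))
                else:
                    vall = float(50.0 * rng.beta(1.0, 6.0))
                    pyr = float(50.0 * rng.beta(1.0, 6.0))
                pas_v: Optional[int] = pas
                vall_v: Optional[float] = vall
                pyr_v: Optional[float] = pyr
                if params.not_rateable_rate > 0:
                    if rng.random() < params.not_rateable_rate:
                        pas_v = None
                    if rng.random() < params.not_rateable_rate:
                        vall_v = pyr_v = None
                person.append(
                    BolusTrial(
                        participant_id=pid,
                        consistency=consistency,
                        bolus_index=b + 1,
                        rating=VfssRating(
                            pas=pas_v, vallecular_fill=vall_v, pyriform_fill=pyr_v
                        ),
                    )
                )
        if params.apply_stopping:
            person = apply_stopping_rules(person)
        trials.extend(person)
    return CohortDataset(trials)


@dataclass
class SignalSimParams:
    """Parameters of the burst-plus-noise accelerometry model."""

    fs: float = 10_000.0
    duration_s: float = 3.0
    n_bursts: int = 1
    burst_duration_s: float = 0.5
    burst_band_hz: tuple = (70.0, 400.0)
    snr: float = 6.0
    noise_sigma: float = 1.0
    drift_amplitude: float = 0.5
    drift_hz: float = 0.05
    class_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise DataError("SNR must be positive")
        lo, hi = self.burst_band_hz
        if not (0.0 < lo < hi < self.fs / 2):
            raise DataError(f"burst band {self.burst_band_hz} outside (0, fs/2)")


def simulate_recording(
    params: SignalSimParams,
    impaired: bool = False,
    trial_id: str = "",
    rng: Optional[np.random.Generator] = None,
) -> tuple[Recording, list[tuple[int, int]]]:
    """Dual-axis recording plus ground-truth burst supports (sample spans).

    Bursts are band-limited noise packets under a Hann amplitude envelope,
    highly correlated across the two axes.  For ``impaired`` trials the
    class effect multiplicatively shifts the burst band upward, shortens
    the burst and rebalances the axis amplitudes, giving the feature layer
    a detectable class-conditional signature proportional to
    ``class_effect``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    def noise() -> np.ndarray:
        white = rng.normal(0.0, params.noise_sigma, n)
        drift = params.drift_amplitude * np.sin(
            2 * np.pi * params.drift_hz * t + rng.uniform(0, 2 * np.pi)
        )
        return white + drift

    si, ap = noise(), noise()
    m = params.class_effect if impaired else 0.0
    lo, hi = params.burst_band_hz
    lo, hi = lo * (1.0 + 0.5 * m), hi * (1.0 + 0.5 * m)
    hi = min(hi, 0.45 * params.fs)
    dur = params.burst_duration_s / (1.0 + 0.4 * m)
    amp = params.snr * params.noise_sigma
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")

    supports: list[tuple[int, int]] = []
    burst_len = int(round(dur * params.fs))
    margin = int(0.1 * params.fs)
    slot = (n - 2 * margin) // max(params.n_bursts, 1)
    for b in range(params.n_bursts):
        lo_start = margin + b * slot
        hi_start = max(lo_start + 1, margin + (b + 1) * slot - burst_len)
        start = int(rng.integers(lo_start, hi_start))
        end = min(start + burst_len, n)
        carrier = sps.sosfilt(sos, rng.normal(0.0, 1.0, end - start))
        carrier /= max(np.std(carrier), 1e-12)
        # flat-topped taper: the annotated support is near full amplitude
        # almost everywhere, so support overlap is a fair detection metric
        envelope = sps.windows.tukey(end - start, alpha=0.25)
        common = amp * envelope * carrier
        # per-axis variation around the common burst
        si_part = common + 0.2 * amp * envelope * rng.normal(0.0, 1.0, end - start)
        ap_gain = 0.8 / (1.0 + 0.5 * m)
        ap_part = ap_gain * common + 0.2 * amp * envelope * rng.normal(
            0.0, 1.0, end - start
        )
        si[start:end] += si_part
        ap[start:end] += ap_part
        supports.append((start, end))
    rec = Recording(
        si_axis=si, ap_axis=ap, fs=params.fs, bit_depth=12, trial_id=trial_id
    )
    return rec, supports


# ---------------------------------------------------------------------------
# Deterministic fixture reconstructing the published prevalence table
# ---------------------------------------------------------------------------

#: Expected summary cells for the fixture: (consistency, outcome) ->
#: (bolus_n, bolus_impaired, bolus_pct, participant_n, participant_impaired,
#:  participant_pct).  These are the published values except the moderately
#: thick efficiency bolus percentage, which is arithmetically unreachable
#: with <= 833 boluses (75/N rounds to 8.9 only for N in 839..847) and
#: therefore reproduces as 9.0.
TABLE2_EXPECTED = {
    (Consistency.thin, "safety"): (1730, 125, 7.2, 305, 70, 23.0),
    (Consistency.thin, "efficiency"): (1716, 115, 6.7, 305, 60, 19.7),
    (Consistency.mildly_thick, "safety"): (864, 51, 5.9, 302, 42, 13.9),
    (Consistency.mildly_thick, "efficiency"): (872, 86, 9.9, 302, 54, 17.9),
    (Consistency.moderately_thick, "safety"): (833, 17, 2.0, 281, 14, 5.0),
    (Consistency.moderately_thick, "efficiency"): (830, 75, 9.0, 280, 51, 18.2),
    (Consistency.extremely_thick, "safety"): (794, 11, 1.4, 268, 10, 3.7),
    (Consistency.extremely_thick, "efficiency"): (794, 67, 8.4, 268, 48, 17.9),
}

#: Thin-safety cumulative detection among complete-series participants:
#: first-detection counts (20, 40, 49, 59, 62, 68) over 266 participants.
CUMULATIVE_EXPECTED = (7.5, 15.0, 18.4, 22.2, 23.3, 25.6)

def _pid(i: int) -> str:
    return f"P{i:03d}"


def _mk(pid, consistency, idx, pas=1, vall=5.0, pyr=0.0):
    return BolusTrial(
        participant_id=pid,
        consistency=consistency,
        bolus_index=idx,
        rating=VfssRating(pas=pas, vallecular_fill=vall, pyriform_fill=pyr),
    )


def _thin_trials() -> list[BolusTrial]:
    C = Consistency.thin
    trials: list[BolusTrial] = []
    # administered bolus counts: participants 1..266 complete (6 boluses),
    # 267..283 have 4, 284..305 have 3 -> 1596 + 68 + 66 = 1730 boluses.
    counts = {}
    for i in range(1, 306):
        counts[i] = 6 if i <= 266 else (4 if i <= 283 else 3)

    # safety: 70 impaired participants (1..68 complete + 267, 268), 125
    # unsafe boluses.  First-positive indices among complete participants
    # cumulate to 20/40/49/59/62/68.
    first_pos = {}
    for i in range(1, 21):
        first_pos[i] = 1
    for i in range(21, 41):
        first_pos[i] = 2
    for i in range(41, 50):
        first_pos[i] = 3
    for i in range(50, 60):
        first_pos[i] = 4
    for i in range(60, 63):
        first_pos[i] = 5
    for i in range(63, 69):
        first_pos[i] = 6
    first_pos[267] = first_pos[268] = 1
    # 55 participants contribute a second unsafe bolus (first_pos + 1)
    doubles = set(range(1, 41)) | set(range(50, 63)) | {267, 268}
    silent = set(range(1, 24))  # 23 silent aspirators

    # efficiency: 60 impaired participants 101..160, 115 inefficient
    # boluses (101..155 on boluses 1-2, 156..160 on bolus 1); participants
    # 161..174 have bolus 6 not-rateable for efficiency (14 NR boluses).
    eff_impaired = set(range(101, 161))
    eff_double = set(range(101, 156))
    eff_nr = set(range(161, 175))

    for i in range(1, 306):
        pid = _pid(i)
        unsafe_at = set()
        if i in first_pos:
            unsafe_at.add(first_pos[i])
            if i in doubles:
                unsafe_at.add(first_pos[i] + 1)
        for b in range(1, counts[i] + 1):
            if b in unsafe_at:
                pas = 8 if (i in silent and b == min(unsafe_at)) else 5
            else:
                pas = 1
            vall, pyr = 5.0, 0.0
            if i in eff_impaired and (b == 1 or (b == 2 and i in eff_double)):
                vall = 60.0
            if i in eff_nr and b == 6:
                vall = pyr = None
            trials.append(_mk(pid, C, b, pas=pas, vall=vall, pyr=pyr))
    return trials


def _thick_trials(
    consistency: Consistency,
    n_participants: int,
    n_short: int,
    saf_double: int,
    saf_single: int,
    n_silent: int,
    eff_double: int,
    eff_single: int,
    saf_nr: Sequence[int] = (),
    eff_nr_pid: Optional[int] = None,
) -> list[BolusTrial]:
    trials: list[BolusTrial] = []
    short_start = n_participants - n_short + 1
    saf_nr = set(saf_nr)
    for i in range(1, n_participants + 1):
        pid = _pid(i)
        n_boluses = 2 if i >= short_start else 3
        for b in range(1, n_boluses + 1):
            pas: Optional[int] = 1
            if i <= saf_double and b <= 2:
                pas = 5
            elif saf_double < i <= saf_double + saf_single and b == 1:
                pas = 5
            if pas == 5 and i <= n_silent and b == 1:
                pas = 8
            if i in saf_nr and b == 3:
                pas = None
            vall: Optional[float] = 5.0
            pyr: Optional[float] = 0.0
            eff_idx = i - 100  # efficiency-impaired block starts at P101
            if 1 <= eff_idx <= eff_double and b <= 2:
                vall = 60.0
            elif eff_double < eff_idx <= eff_double + eff_single and b == 1:
                vall = 60.0
            if eff_nr_pid is not None and i == eff_nr_pid:
                vall = pyr = None
            trials.append(_mk(pid, consistency, b, pas=pas, vall=vall, pyr=pyr))
    return trials


def make_table2_fixture() -> CohortDataset:
    """Deterministic cohort reproducing the published prevalence structure.

    Integer counts (boluses, participants, impaired at both levels, silent
    aspirators, not-rateable cells, first-detection indices) are chosen so
    that the label-derivation + roll-up + summary chain reproduces every
    reported percentage that is arithmetically attainable; see
    ``TABLE2_EXPECTED`` and ``CUMULATIVE_EXPECTED`` for the two cells where
    the published rounding is internally inconsistent.
    """
    trials = _thin_trials()
    # mildly thick: 302 participants, 34 with 2 boluses -> 872; 8 safety-NR
    # boluses (P175..P182 bolus 3) -> 864 rateable; 42 impaired (P1..42, 51
    # unsafe boluses), 16 silent; efficiency 54 impaired (P101..154, 86
    # inefficient boluses).
    trials += _thick_trials(
        Consistency.mildly_thick,
        n_participants=302,
        n_short=34,
        saf_double=9,
        saf_single=33,
        n_silent=16,
        eff_double=32,
        eff_single=22,
        saf_nr=range(175, 183),
    )
    # moderately thick: 281 participants, 10 with 2 boluses -> 833; safety
    # 14 impaired / 17 boluses, 2 silent; efficiency 51 impaired / 75
    # boluses; P200 entirely efficiency-NR (3 boluses) -> denominators
    # 830 boluses / 280 participants.
    trials += _thick_trials(
        Consistency.moderately_thick,
        n_participants=281,
        n_short=10,
        saf_double=3,
        saf_single=11,
        n_silent=2,
        eff_double=24,
        eff_single=27,
        eff_nr_pid=200,
    )
    # extremely thick: 268 participants, 10 with 2 boluses -> 794; safety
    # 10 impaired / 11 boluses, 1 silent; efficiency 48 impaired / 67.
    trials += _thick_trials(
        Consistency.extremely_thick,
        n_participants=268,
        n_short=10,
        saf_double=1,
        saf_single=9,
        n_silent=1,
        eff_double=19,
        eff_single=29,
    )
    return CohortDataset(trials)
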