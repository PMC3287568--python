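"""Synthetic microarray-like cohorts with planted class structure.

The generator emulates the structure of a multi-institution lung
adenocarcinoma expression cohort: a few hundred samples, tens of thousands
of probes, a small planted subset of informative probes whose class means
differ, and censored recurrence times.  Two latent risk classes drive
everything: informative probes are mean-shifted in the high-risk class, and
time to recurrence is exponential with a class-specific hazard, observed
through independent exponential censoring.  Survival is generated from the
class labels rather than from expression directly, so the expected behavior
of the downstream classifier -> Kaplan-Meier / Cox chain is analytically
known.

Default condition: 300 samples x 20,000 probes, 50 informative probes with
a one-standard-deviation class shift, 40% high risk, recurrence hazards
0.08 and 0.02 events/month (hazard ratio 4; median times ~8.7 and ~35
months), censoring hazard 0.01/month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ClinicalTable, ExpressionMatrix

#: Baseline expression level, arbitrary units.  With unit noise SD this
#: puts every probe's coefficient of variation near 1, so the coarse
#: variance-pruning stage at its usual cutoff passes simulated probes
#: through rather than deleting the planted structure wholesale.
BASELINE_EXPRESSION = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated cohort."""

    n_samples: int = 300
    n_features: int = 20_000
    n_informative: int = 50
    #: Standardized mean shift of informative probes between classes.
    effect_size: float = 1.0
    #: Fraction of samples in the high-risk class.
    class_balance: float = 0.4
    #: Recurrence hazards, events per month.
    base_hazard_high: float = 0.08
    base_hazard_low: float = 0.02
    #: Independent censoring hazard, events per month.
    censor_rate: float = 0.01
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValidationError("need n_samples >= 2 and n_features >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("n_informative must lie in [0, n_features]")
        if not 0 < self.class_balance < 1:
            raise ValidationError("class_balance must lie in (0, 1)")
        for name in ("base_hazard_high", "base_hazard_low", "censor_rate",
                     "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort (for evaluation only)."""

    informative_ids: list[str]
    class_labels: np.ndarray  # +1 high risk / -1 low risk, sample order
    spec: SyntheticSpec = field(repr=False, default=None)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort under ``spec``; reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    n_high = int(round(n * spec.class_balance))
    n_high = min(max(n_high, 1), n - 1)
    classes = np.full(n, -1, dtype=int)
    classes[rng.permutation(n)[:n_high]] = 1

    values = BASELINE_EXPRESSION + rng.normal(0.0, spec.noise_sd, size=(n, p))
    informative = rng.choice(p, size=spec.n_informative, replace=False)
    shift = spec.effect_size * spec.noise_sd
    values[np.ix_(classes == 1, informative)] += shift

    width = max(5, len(str(p)))
    feature_ids = [f"probe_{j:0{width}d}_at" for j in range(p)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    hazards = np.where(classes == 1, spec.base_hazard_high, spec.base_hazard_low)
    event_times = rng.exponential(1.0 / hazards)
    censor_times = rng.exponential(1.0 / spec.censor_rate, size=n)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "time_months": observed,
        "event": event,
        "age": np.round(rng.normal(64.0, 10.0, size=n), 1),
        "gender": rng.choice(["F", "M"], size=n),
        "stage": rng.choice([1, 2, 3], size=n, p=[0.55, 0.30, 0.15]),
    }))
    truth = SyntheticTruth(
        informative_ids=[feature_ids[j] for j in sorted(informative)],
        class_labels=classes.astype(float),
        spec=spec,
    )
    return ExpressionMatrix(values, feature_ids, sample_ids), clinical, truth


def generate_worked_weights(
    n_features: int, seed: int = 0, tie_positions: tuple[int, ...] = (),
) -> tuple[np.ndarray, dict]:
    """Deterministic weight-vector fixture with a known importance ranking.

    Magnitudes decrease strictly with position (position 0 is the most
    influential) except at ``tie_positions``, where consecutive positions
    share a magnitude; signs are random.  The metadata records the ranking
    by decreasing magnitude and which positions are tied.
    """
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    magnitudes = np.linspace(float(n_features), 1.0, n_features)
    for pos in tie_positions:
        if not 1 <= pos < n_features:
            raise ValidationError(f"tie position {pos} out of range")
        magnitudes[pos] = magnitudes[pos - 1]
    signs = rng.choice([-1.0, 1.0], size=n_features)
    weights = magnitudes * signs
    metadata = {
        "ranking": np.argsort(-magnitudes, kind="stable"),
        "tied_positions": sorted(set(tie_positions)),
    }
    return weights, metadata
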