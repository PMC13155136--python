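"""Synthetic limiting-dilution data with the model's exact generative structure.

For each treatment, replicate and dilution ``S`` the number of negative wells
is drawn ``Y ~ Binomial(n, mu)`` with ``mu = exp(-p_t * S**b)``.  Treatment
scaling is parameterized by the *true survival fraction*: a treatment with
``sf_true`` uses ``p_t = p * sf_true**b``, which makes its activity exactly
``a / sf_true`` and hence its survival fraction exactly ``sf_true``
(``SF = (p_t/p)**(1/b)``).

Wells receive the expected cell number deterministically — no seeding noise —
which is precisely the assumption of the fitted model, so simulate-then-fit
recovers the generating parameters up to binomial sampling error.  The random
stream order is fixed and documented (treatment-major, then replicate, then
dilution) so that a given seed always yields bit-identical counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AssayGroup, DilutionObservation, LDAExperiment, pool_replicates
from .exceptions import EstimationRefusedError, InputError
from .model import LimitingDilutionModel
from .activity import clonogenic_activity
from .survival import SF_COMPONENT_LEVEL, survival_fraction

__all__ = ["SimulationConfig", "simulate_lda", "design_grid", "failure_probability"]

#: Default geometric dilution ladder: 2**0 .. 2**7 cells per well, the
#: 8-dilution x 12-well layout of a standard 96-well assay plate.
DEFAULT_DILUTIONS = tuple(float(2**k) for k in range(8))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic LDA experiment.

    Defaults describe the standard assay: per-cell activity scale ``p = 0.1``,
    linear growth ``b = 1``, dilutions ``2**0..2**7``, 12 wells per dilution,
    one biological replicate, a single untreated condition.
    """

    p: float = 0.1
    b: float = 1.0
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    n_wells: int = 12
    n_replicates: int = 1
    treatments: tuple[tuple[str, float], ...] = (("control", 1.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p > 0 and np.isfinite(self.p)):
            raise InputError(f"p must be positive, got {self.p!r}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise InputError(f"b must be positive, got {self.b!r}")
        dil = tuple(float(s) for s in self.dilutions)
        if len(dil) == 0 or any(s <= 0 or not np.isfinite(s) for s in dil):
            raise InputError("dilutions must be positive and finite")
        if len(set(dil)) != len(dil):
            raise InputError("dilutions must be distinct")
        object.__setattr__(self, "dilutions", dil)
        if int(self.n_wells) != self.n_wells or self.n_wells < 1:
            raise InputError(f"n_wells must be a positive integer, got {self.n_wells!r}")
        if int(self.n_replicates) != self.n_replicates or self.n_replicates < 1:
            raise InputError(
                f"n_replicates must be a positive integer, got {self.n_replicates!r}"
            )
        trt = tuple((str(label), float(sf)) for label, sf in self.treatments)
        if len(trt) == 0:
            raise InputError("at least one treatment is required")
        if len({label for label, _ in trt}) != len(trt):
            raise InputError("treatment labels must be unique")
        if any(sf <= 0 for _, sf in trt):
            raise InputError("sf_true must be positive for every treatment")
        object.__setattr__(self, "treatments", trt)


def failure_probability(p: float, b: float, S) -> np.ndarray:
    """mu(S) = exp(-p * S**b), the no-growth probability of one well."""
    S = np.asarray(S, dtype=float)
    return np.exp(-p * np.power(S, b))


def simulate_lda(config: SimulationConfig) -> LDAExperiment:
    """Draw one synthetic experiment under the power-law growth model.

    Negative-well counts are sampled treatment-major, then replicate, then
    dilution, from ``numpy.random.default_rng(config.seed)``; the same seed
    therefore reproduces the experiment bit-exactly.  The generating truth
    (p, b, per-treatment survival fractions and activities) is attached as
    ``experiment.metadata["truth"]``.
    """
    rng = np.random.default_rng(config.seed)
    groups = []
    truth_treatments = {}
    for label, sf_true in config.treatments:
        p_t = config.p * sf_true**config.b
        truth_treatments[label] = {
            "p": p_t,
            "sf_true": sf_true,
            "activity": float(p_t ** (-1.0 / config.b)),
        }
        for r in range(config.n_replicates):
            obs = []
            for S in config.dilutions:
                mu = float(failure_probability(p_t, config.b, S))
                y = int(rng.binomial(config.n_wells, mu))
                obs.append(DilutionObservation(S, config.n_wells, y))
            groups.append(AssayGroup(label, f"rep{r + 1}", tuple(obs)))
    reference = config.treatments[0][0]
    return LDAExperiment(
        groups=groups,
        reference_treatment=reference,
        metadata={
            "truth": {
                "p": config.p,
                "b": config.b,
                "seed": config.seed,
                "treatments": truth_treatments,
            }
        },
    )


def write_truth_sidecar(experiment: LDAExperiment, path) -> None:
    """Write the generating truth metadata next to a simulated CSV."""
    import json

    with open(path, "w") as fh:
        json.dump(experiment.metadata.get("truth", {}), fh, indent=2)


def design_grid(
    base: SimulationConfig,
    n_values: list[int],
    d_values: list[int],
    reps: int = 20,
) -> pd.DataFrame:
    """Mean confidence-interval widths across an assay-design grid.

    For each combination of wells-per-dilution ``n`` and number of informative
    dilutions ``d`` (the first ``d`` steps of the base ladder), ``reps``
    experiments are simulated and fitted (replicates pooled); the mean width
    of the 95% activity CI and, when the base config includes a treated
    condition, of the 95% survival-fraction CI are reported.  Seeds for each
    grid cell are spawned deterministically from ``base.seed``.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    if any(n < 1 for n in n_values):
        raise InputError("n_values must be positive")
    if any(d < 1 or d > len(base.dilutions) for d in d_values):
        raise InputError(
            f"d_values must be within 1..{len(base.dilutions)} (available ladder)"
        )
    rows = []
    for n in n_values:
        for d in d_values:
            # fresh SeedSequence per cell: every design cell sees the same
            # child seeds, so comparisons across (n, d) are paired
            child_seeds = [int(s.generate_state(1)[0] % 2**31)
                           for s in np.random.SeedSequence(base.seed).spawn(reps)]
            widths_a, widths_sf = [], []
            for seed in child_seeds:
                cfg = SimulationConfig(
                    p=base.p,
                    b=base.b,
                    dilutions=base.dilutions[:d],
                    n_wells=n,
                    n_replicates=base.n_replicates,
                    treatments=base.treatments,
                    seed=seed,
                )
                exp = simulate_lda(cfg)
                try:
                    fit_ref = LimitingDilutionModel(
                        pool_replicates(exp.groups_for(exp.reference_treatment))
                    ).fit()
                    est = clonogenic_activity(fit_ref, level=0.95)
                except (EstimationRefusedError, InputError):
                    continue
                if np.isfinite(est.ci[1]) and est.ci[0] > 0:
                    widths_a.append(est.ci[1] - est.ci[0])
                treated = [t for t, _ in cfg.treatments if t != exp.reference_treatment]
                if treated:
                    try:
                        fit_t = LimitingDilutionModel(
                            pool_replicates(exp.groups_for(treated[0]))
                        ).fit()
                        res = survival_fraction(fit_ref, fit_t, SF_COMPONENT_LEVEL)
                    except (EstimationRefusedError, InputError):
                        continue
                    if np.isfinite(res.ci95[1]) and res.ci95[0] > 0:
                        widths_sf.append(res.ci95[1] - res.ci95[0])
            rows.append(
                {
                    "n_wells": n,
                    "n_dilutions": d,
                    "reps_used": len(widths_a),
                    "mean_activity_ci_width": float(np.mean(widths_a))
                    if widths_a else np.nan,
                    "mean_sf_ci_width": float(np.mean(widths_sf))
                    if widths_sf else np.nan,
                }
            )
    return pd.DataFrame(rows)
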