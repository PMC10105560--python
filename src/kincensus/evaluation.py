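"""Experiment grids and bias/precision summaries.

Accuracy is the mean relative bias N_hat/N (1 = unbiased) over replicate
populations and repeated samples; precision is the coefficient of variation
of the relative bias, computed per population across its resamples and then
averaged (+- SD) across populations, expressed as a percentage.  20% CV is
the conventional threshold for management utility.

Every quantity here is a pure function of a ScenarioConfig, including its
seed: population seeds and resample seeds are derived deterministically from
the root seed and the scenario coordinates, so arbitrary grid cells can be
recomputed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import (Pedigree, SpeciesParams, TruthSizes,
                         make_species_params, simulate, truth_sizes)
from .estimators import TARGET_BY_METHOD, Estimate, estimate_all
from .sampling import draw_sample, find_pops, kin_counts

__all__ = ["ScenarioConfig", "relative_bias", "resample_population",
           "summarize_records", "run_species_comparison",
           "run_fecundity_sweep", "run_sd_sweep", "bin_by_pops"]

METHODS = tuple(TARGET_BY_METHOD)

_DEFAULT_SAMPLING_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameterization of one experiment grid.

    Defaults are reduced-scale (30 populations x 30 resamples) so a full
    grid runs on a desktop; the full-scale study design is 100 x 100.
    """

    base_species: SpeciesParams | str = "red_deer"
    species: tuple[str, ...] = ("red_deer", "wild_boar")
    fecundity_grid: tuple[float, ...] = tuple(range(1, 15))
    fecundity_sd_grid: tuple[float, ...] = (0.0, 2.0, 4.0)
    sampling_grid: tuple[float, ...] = _DEFAULT_SAMPLING_GRID
    comparison_fraction: float = 0.3
    n_populations: int = 30
    n_resamples: int = 30
    n_years: int = 200
    seed: int = 0

    def __post_init__(self):
        problems = []
        for name in ("fecundity_grid", "fecundity_sd_grid", "sampling_grid"):
            if len(getattr(self, name)) == 0:
                problems.append(f"{name} is empty")
        bad = [q for q in self.sampling_grid if not 0 < q <= 1]
        if bad or not 0 < self.comparison_fraction <= 1:
            problems.append(f"sampling fractions must be in (0, 1]: "
                            f"{bad or self.comparison_fraction}")
        for name in ("n_populations", "n_resamples", "n_years"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if problems:
            raise ValueError("invalid ScenarioConfig: " + "; ".join(problems))

    def resolve_base(self) -> SpeciesParams:
        if isinstance(self.base_species, SpeciesParams):
            return self.base_species
        return make_species_params(self.base_species)


def child_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2**31) from a tuple of integer coordinates."""
    state = np.random.SeedSequence(list(keys)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def relative_bias(estimate: Estimate, truth: TruthSizes) -> float:
    """N_hat normalized by the true size of the estimate's target class.

    Returns NaN (flagged missing) for undefined estimates or zero truth.
    """
    if not estimate.defined:
        return float("nan")
    true_n = truth.for_target(estimate.target)
    if true_n <= 0:
        return float("nan")
    return estimate.n_hat / true_n


def resample_population(pedigree: Pedigree, fraction: float, n_resamples: int,
                        seed: int) -> pd.DataFrame:
    """Repeatedly sample one simulated population and apply all estimators.

    Returns one row per (resample, method) with the estimate, its relative
    bias against the population's truth sizes, and the sample's total POP
    count.  Undefined estimates are carried with NaN bias.
    """
    truth = truth_sizes(pedigree)
    rows = []
    for r in range(n_resamples):
        sample = draw_sample(pedigree, fraction, child_seed(seed, r))
        pops = find_pops(sample, pedigree)
        counts = kin_counts(sample, pops, pedigree)
        for est in estimate_all(sample, pedigree, counts=counts):
            rows.append((r, est.method, est.target, est.n_hat, est.defined,
                         truth.for_target(est.target),
                         relative_bias(est, truth), counts.h_total))
    return pd.DataFrame(rows, columns=["resample", "method", "target", "n_hat",
                                       "defined", "truth", "bias", "n_pops"])


def summarize_records(records: pd.DataFrame, by: list[str] | None = None,
                      pooled_cv: bool = False) -> pd.DataFrame:
    """Aggregate per-resample records into bias/precision summaries.

    Requires a ``population`` column.  ``mean_bias``/``sd_bias`` pool all
    defined biases in the cell; ``cv_pct`` is the mean over populations of
    the per-population CV% across resamples (``pooled_cv=True`` switches to
    a single CV over all defined biases).  Undefined estimates are excluded
    from the moments and counted in ``n_undefined``.
    """
    by = list(by) if by is not None else ["method"]

    def _cell(g: pd.DataFrame) -> pd.Series:
        defined = g.loc[g["defined"], "bias"]
        per_pop = g[g["defined"]].groupby("population")["bias"].agg(["mean", "std"])
        per_pop_cv = 100.0 * per_pop["std"] / per_pop["mean"]
        if pooled_cv:
            cv = 100.0 * defined.std() / defined.mean() if len(defined) > 1 else np.nan
            cv_sd = np.nan
        else:
            cv = per_pop_cv.mean()
            cv_sd = per_pop_cv.std()
        return pd.Series({
            "mean_bias": defined.mean(),
            "sd_bias": defined.std(),
            "cv_pct": cv,
            "sd_cv_pct": cv_sd,
            "n_defined": int(g["defined"].sum()),
            "n_undefined": int((~g["defined"]).sum()),
            "mean_pops": g["n_pops"].mean(),
        })

    out = (records.groupby(by, sort=True, observed=True)
           .apply(_cell, include_groups=False).reset_index())
    for c in ("n_defined", "n_undefined"):
        out[c] = out[c].astype(int)
    return out


def _simulate_populations(params: SpeciesParams, config: ScenarioConfig,
                          scenario_key: tuple[int, ...]) -> list[Pedigree]:
    return [simulate(params, config.n_years,
                     child_seed(config.seed, *scenario_key, p))
            for p in range(config.n_populations)]


def _records_for(params: SpeciesParams, config: ScenarioConfig,
                 fractions: tuple[float, ...],
                 scenario_key: tuple[int, ...],
                 extra: dict) -> pd.DataFrame:
    """Simulate the replicate populations once, resample at each fraction."""
    pedigrees = _simulate_populations(params, config, scenario_key)
    frames = []
    for qi, q in enumerate(fractions):
        for p, ped in enumerate(pedigrees):
            rec = resample_population(
                ped, q, config.n_resamples,
                child_seed(config.seed, *scenario_key, qi, p, 1))
            rec.insert(0, "population", p)
            rec.insert(1, "fraction", q)
            frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    for k, v in extra.items():
        records[k] = v
    return records


def run_species_comparison(config: ScenarioConfig,
                           return_records: bool = False):
    """Benchmark all four methods on each species preset at one fraction.

    For each species: ``n_populations`` simulated pedigrees, each resampled
    ``n_resamples`` times at ``comparison_fraction``.  Returns one summary
    row per (species, method).
    """
    frames = []
    for si, name in enumerate(config.species):
        params = make_species_params(name)
        rec = _records_for(params, config, (config.comparison_fraction,),
                           scenario_key=(0, si), extra={"species": name})
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize_records(records, by=["species", "method"])
    return (summary, records) if return_records else summary


def run_fecundity_sweep(config: ScenarioConfig, fecundity_sd: float = 0.0,
                        return_records: bool = False):
    """Full factorial fecundity-mean x sampling-fraction grid.

    Base demographics come from ``config.base_species`` with the fecundity
    mean swept over ``fecundity_grid`` at the given fixed SD.  Populations
    are simulated once per fecundity and re-used across fractions.
    """
    base = config.resolve_base()
    frames = []
    for fi, fec in enumerate(config.fecundity_grid):
        params = base.replace(fecundity_mean=float(fec),
                              fecundity_sd=float(fecundity_sd),
                              name=f"{base.name}_fec{fec:g}")
        rec = _records_for(params, config, tuple(config.sampling_grid),
                           scenario_key=(1, fi),
                           extra={"fecundity_mean": float(fec),
                                  "fecundity_sd": float(fecundity_sd)})
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize_records(
        records, by=["fecundity_mean", "fecundity_sd", "fraction", "method"])
    return (summary, records) if return_records else summary


def run_sd_sweep(config: ScenarioConfig, fecundity_mean: float = 7.0,
                 return_records: bool = False):
    """Fecundity-SD x sampling-fraction grid at a fixed fecundity mean."""
    base = config.resolve_base()
    frames = []
    for di, sd in enumerate(config.fecundity_sd_grid):
        params = base.replace(fecundity_mean=float(fecundity_mean),
                              fecundity_sd=float(sd),
                              name=f"{base.name}_sd{sd:g}")
        rec = _records_for(params, config, tuple(config.sampling_grid),
                           scenario_key=(2, di),
                           extra={"fecundity_mean": float(fecundity_mean),
                                  "fecundity_sd": float(sd)})
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize_records(
        records, by=["fecundity_mean", "fecundity_sd", "fraction", "method"])
    return (summary, records) if return_records else summary


def bin_by_pops(records: pd.DataFrame, bin_width: int = 10) -> pd.DataFrame:
    """Bias summaries grouped by POP-count bins (empty bins omitted).

    Bins are left-closed intervals of ``bin_width`` POPs starting at 0; the
    ``pop_bin`` column holds each bin's lower edge.  Grouping keys include
    ``fecundity_mean`` when present.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rec = records.copy()
    rec["pop_bin"] = (rec["n_pops"] // bin_width) * bin_width
    by = ["method", "pop_bin"]
    if "fecundity_mean" in rec.columns:
        by = ["fecundity_mean"] + by
    return summarize_records(rec, by=by)
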