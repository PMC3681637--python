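"""Pre-registered simulation scenarios.

Three study designs, each run as replicate batches and summarised as a
tidy table of final mutant-allele frequencies (mean and standard error over
replicates) plus the end-state survivorship/fertility curves:

* ``scenario_mortality_only`` — five sex-indifferent mortality loci with
  onsets in mid-life, under an age-indifferent (AP) or young-pairs (YP)
  preference matrix, with intrinsically declining female fertility but
  prolonged male fertility.  Contrasts mutation-selection balance (AP)
  against selection-free accumulation and a late-life death barrier (YP).
* ``scenario_fertility_and_mortality`` — fifteen loci (mortality,
  male-limited infertility, female-limited infertility) on a prolonged-
  fertility ancestral state, under AP or young-females (YF) preference.
  Under YF, late-onset female-limited infertility alleles become nearly
  neutral and accumulate: the origin of a menopausal fertility decline.
* ``scenario_matrix_shift`` — a single female-limited infertility locus,
  with the matrix switched from AP to YF part-way through; returns the
  replicate-averaged frequency trajectory through the shift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import ReplicateSummary, SimConfig, run_replicates
from .genetics import FEMALE, MALE, LocusSpec
from .life_tables import mortality_study_tables, prolonged_tables
from .mating import build_matrix

__all__ = [
    "mortality_loci",
    "three_category_loci",
    "summary_table",
    "curves_table",
    "scenario_mortality_only",
    "scenario_fertility_and_mortality",
    "scenario_matrix_shift",
]

ONSETS_DEFAULT = (6, 7, 8, 9, 10)
MU_DEFAULT = 0.005
E_DEFAULT = 0.025


def mortality_loci(
    onsets=ONSETS_DEFAULT, e: float = E_DEFAULT, mu: float = MU_DEFAULT
) -> list[LocusSpec]:
    """Sex-indifferent mortality loci, one per onset class."""
    return [
        LocusSpec(i + 1, "mortality", "both", onset, e=e, mu=mu)
        for i, onset in enumerate(onsets)
    ]


def three_category_loci(
    onsets=ONSETS_DEFAULT, e: float = E_DEFAULT, mu: float = MU_DEFAULT
) -> list[LocusSpec]:
    """Mortality + male-limited and female-limited infertility loci.

    Fifteen loci by default: for each onset class, one sex-indifferent
    mortality locus, one male-only fertility locus and one female-only
    fertility locus, all with the same e and mu.
    """
    loci = mortality_loci(onsets, e, mu)
    nid = len(loci)
    for scope in ("male_only", "female_only"):
        for onset in onsets:
            nid += 1
            loci.append(LocusSpec(nid, "fertility", scope, onset, e=e, mu=mu))
    return loci


def summary_table(summary: ReplicateSummary, loci: list[LocusSpec]) -> pd.DataFrame:
    """Tidy per-locus, per-sex summary of final frequencies."""
    rows = []
    for k, locus in enumerate(loci):
        category = (
            "mortality"
            if locus.effect == "mortality"
            else f"fertility_{locus.scope.removesuffix('_only')}"
        )
        for sex, name in ((MALE, "male"), (FEMALE, "female")):
            rows.append(
                {
                    "locus": locus.id,
                    "onset_class": locus.onset_class,
                    "category": category,
                    "sex": name,
                    "mean_freq": summary.mean[k, sex],
                    "se": summary.se[k, sex],
                }
            )
    return pd.DataFrame(rows)


def curves_table(summary: ReplicateSummary) -> pd.DataFrame:
    """End-state survival/fertility curves averaged over replicates."""
    surv = np.nanmean(np.stack([r.end_survivorship for r in summary.results]), axis=0)
    fert = np.nanmean(np.stack([r.end_fertility for r in summary.results]), axis=0)
    n = surv.shape[1]
    rows = []
    for sex, name in ((MALE, "male"), (FEMALE, "female")):
        for c in range(n):
            rows.append(
                {
                    "sex": name,
                    "age_class": c + 1,
                    "survival": surv[sex, c],
                    "fertility": fert[sex, c],
                }
            )
    return pd.DataFrame(rows)


def _run_scenario(
    loci, tables, model, N, n_periods, n_reps, seed, burn_in, record_every
):
    config = SimConfig(
        N=N,
        loci=loci,
        tables=tables,
        matrix=build_matrix(model, n_classes=tables.n_classes),
        n_periods=n_periods,
        burn_in=burn_in,
        seed=seed,
        record_every=record_every,
    )
    summary = run_replicates(config, n_reps, seed_base=seed)
    return summary_table(summary, loci), curves_table(summary), summary


def scenario_mortality_only(
    model: str = "AP",
    N: int = 1000,
    n_periods: int = 10000,
    n_reps: int = 10,
    seed: int = 0,
    e: float = E_DEFAULT,
    mu: float = MU_DEFAULT,
    burn_in: int = 200,
    record_every: int = 100,
):
    """Five mortality loci (onsets 6-10) under AP or YP.

    Returns ``(summary, curves, replicates)``: the per-locus final-frequency
    table, the end-state curve table, and the raw replicate summary.
    """
    if model not in ("AP", "YP"):
        raise ValueError("mortality-only scenario uses model AP or YP")
    loci = mortality_loci(e=e, mu=mu)
    return _run_scenario(
        loci, mortality_study_tables(), model, N, n_periods, n_reps, seed,
        burn_in, record_every,
    )


def scenario_fertility_and_mortality(
    model: str = "AP",
    N: int = 1000,
    n_periods: int = 10000,
    n_reps: int = 10,
    seed: int = 0,
    e: float = E_DEFAULT,
    mu: float = MU_DEFAULT,
    burn_in: int = 200,
    record_every: int = 100,
):
    """Fifteen loci (mortality + sex-limited infertility) under AP or YF,
    starting from prolonged fertility in both sexes."""
    if model not in ("AP", "YF"):
        raise ValueError("fertility scenario uses model AP or YF")
    loci = three_category_loci(e=e, mu=mu)
    return _run_scenario(
        loci, prolonged_tables(), model, N, n_periods, n_reps, seed,
        burn_in, record_every,
    )


def scenario_matrix_shift(
    N: int = 1000,
    mu: float = MU_DEFAULT,
    e: float = E_DEFAULT,
    onset_class: int = 6,
    shift_period: int = 1000,
    n_periods: int = 3000,
    n_reps: int = 20,
    seed: int = 0,
    burn_in: int = 200,
    record_every: int = 10,
) -> tuple[pd.DataFrame, ReplicateSummary]:
    """Single female-limited infertility locus; AP until ``shift_period``,
    YF afterwards.

    Returns the replicate-mean female-frequency trajectory (DataFrame with
    columns period, mean_freq, se) and the raw replicate summary.
    """
    if not 0 <= shift_period < n_periods:
        raise ValueError("shift_period must lie in [0, n_periods)")
    tables = prolonged_tables()
    locus = LocusSpec(1, "fertility", "female_only", onset_class, e=e, mu=mu)
    config = SimConfig(
        N=N,
        loci=[locus],
        tables=tables,
        matrix=build_matrix("AP", n_classes=tables.n_classes),
        n_periods=n_periods,
        burn_in=burn_in,
        seed=seed,
        shift=(shift_period, build_matrix("YF", n_classes=tables.n_classes)),
        record_every=record_every,
    )
    summary = run_replicates(config, n_reps, seed_base=seed)
    female = np.stack([r.freq[:, 0, FEMALE] for r in summary.results])  # (reps, T)
    periods = summary.results[0].periods
    traj = pd.DataFrame(
        {
            "period": periods,
            "mean_freq": female.mean(axis=0),
            "se": (
                female.std(axis=0, ddof=1) / np.sqrt(n_reps)
                if n_reps > 1
                else np.nan
            ),
        }
    )
    return traj, summary
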