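"""Mutation-rate arithmetic and the endogenous-vs-UV partition.

Division counts come from a telomere-attrition model: newborn telomere
restriction fragments (TRFs) are ~11 kb; the measured repeat length gets
+1 kb for the restriction-site-to-repeat DNA and +2 kb to undo culture
attrition (>= 20 clonal generations x 100 bp), giving the progenitor TRF;
fibroblasts lose 50-100 bp per division, so

    divisions = (newborn TRF - progenitor TRF) / attrition.

With the default 100 bp/division this is a minimum division count, hence
the per-division rate

    rate = load / (divisions x 6e9 nt diploid genome)

is a maximal estimate (prenatal divisions are unknown). Yearly rates
divide loads by donor age; UV-attributable and endogenous yearly rates
split the load using the UV minimum mutation load. Donor-level summaries
average hip endogenous (conservative, Approach 1) or hip total (maximal,
Approach 2) rates against forearm UV rates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIPLOID_GENOME_NT = 6e9


@dataclass(frozen=True)
class TelomereModel:
    """Telomere-attrition parameters (bp)."""

    newborn_trf: float = 11_000.0
    subtelomere_offset: float = 1_000.0   # restriction site to repeat start
    culture_correction: float = 2_000.0   # >= 20 culture generations x 100 bp
    attrition_per_division: float = 100.0  # 50-100 bp/division

    def __post_init__(self):
        if min(self.newborn_trf, self.subtelomere_offset,
               self.culture_correction) < 0:
            raise ValueError("lengths must be non-negative")
        if self.attrition_per_division <= 0:
            raise ValueError("attrition must be positive")


def progenitor_trf(measured_telomere: float,
                   model: TelomereModel = TelomereModel()) -> float:
    """Progenitor-cell TRF length: measured repeat length + subtelomeric
    offset + culture-attrition correction."""
    return measured_telomere + model.subtelomere_offset \
        + model.culture_correction


def estimate_divisions(measured_telomere: float,
                       model: TelomereModel = TelomereModel()) -> int:
    """Post-natal cell divisions from telomere attrition, rounded to the
    nearest integer."""
    prog = progenitor_trf(measured_telomere, model)
    return divisions_from_progenitor_trf(prog, model)


def divisions_from_progenitor_trf(progenitor: float,
                                  model: TelomereModel = TelomereModel()) -> int:
    if progenitor >= model.newborn_trf:
        raise ValueError(
            "progenitor TRF must be shorter than the newborn TRF "
            "(no attrition to count)")
    return int(round((model.newborn_trf - progenitor)
                     / model.attrition_per_division))


def rate_per_nt_per_division(load: float, divisions: float,
                             diploid_genome: float = DIPLOID_GENOME_NT) -> float:
    """Mutations per nucleotide per cell division (a maximal estimate:
    prenatal divisions are not counted)."""
    if divisions <= 0:
        raise ValueError("divisions must be positive")
    if load < 0:
        raise ValueError("load must be non-negative")
    return load / (divisions * diploid_genome)


def rate_per_year(load: float, age: float) -> int:
    """Mutations per genome per year, rounded to the nearest integer."""
    if age <= 0:
        raise ValueError("age must be positive")
    if load < 0:
        raise ValueError("load must be non-negative")
    return int(round(load / age))


def yearly_partition(load: float, uv_min_load: float,
                     age: float) -> tuple[int, int, int]:
    """(UV rate, endogenous rate, total rate) per year: the UV minimum load
    over age, the remainder over age, and the total over age, each rounded
    to the nearest integer."""
    if not 0 <= uv_min_load <= load:
        raise ValueError("uv_min_load must lie in [0, load]")
    uv = rate_per_year(uv_min_load, age)
    endo = rate_per_year(load - uv_min_load, age)
    total = rate_per_year(load, age)
    return uv, endo, total


@dataclass
class RateEstimate:
    """Per-clone rate summary."""

    sample: str
    donor: str
    site: str              # 'hip' or 'forearm'
    load: float
    age: float
    uv_min_load: float = 0.0
    divisions: int | None = None

    @property
    def uv_rate(self) -> int:
        return rate_per_year(self.uv_min_load, self.age)

    @property
    def endogenous_rate(self) -> int:
        return rate_per_year(self.load - self.uv_min_load, self.age)

    @property
    def total_rate(self) -> int:
        return rate_per_year(self.load, self.age)

    @property
    def rate_per_nt_per_division(self) -> float:
        if self.divisions is None:
            raise ValueError("divisions not set")
        return rate_per_nt_per_division(self.load, self.divisions)


def rates_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": e.sample, "donor": e.donor, "site": e.site,
        "load": e.load, "age": e.age, "uv_min_load": e.uv_min_load,
        "uv_rate": e.uv_rate, "endogenous_rate": e.endogenous_rate,
        "total_rate": e.total_rate,
    } for e in estimates])


def partition_summary(rates: pd.DataFrame, approach: int) -> pd.DataFrame:
    """Per-donor endogenous-vs-UV averages, one decimal.

    Approach 1 (conservative): mean of hip endogenous yearly rates vs mean
    of forearm UV yearly rates. Approach 2 (maximal): mean of hip total
    yearly rates vs mean of forearm UV yearly rates.

    `rates` needs columns donor, site ('hip'/'forearm'), uv_rate,
    endogenous_rate, total_rate (as from :func:`rates_frame`).
    """
    if approach not in (1, 2):
        raise ValueError("approach must be 1 or 2")
    endo_col = "endogenous_rate" if approach == 1 else "total_rate"
    rows = []
    for donor, grp in rates.groupby("donor"):
        hips = grp.loc[grp["site"] == "hip"]
        arms = grp.loc[grp["site"] == "forearm"]
        if len(hips) == 0 or len(arms) == 0:
            raise ValueError(
                f"donor {donor!r} lacks hip or forearm samples")
        rows.append({
            "donor": donor, "approach": approach,
            "endogenous_avg": round(float(hips[endo_col].mean()), 1),
            "uv_avg": round(float(arms["uv_rate"].mean()), 1),
        })
    return pd.DataFrame(rows)
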