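"""Annual/monthly flux budgets and positive-input source apportionment.

The annual budget table mirrors the layout of the published interface-flux
table: one row per process, one column per congener group, in
ng m-2 yr-1, positive = input to the water column.  Sigma rows give the
net air-water and net sediment-water exchange.  Source apportionment
follows the positive-inputs rule: air = absorption + wet + dry deposition,
sediment = (diffusion clamped at >= 0) + resuspension, river = river load;
shares are normalized to sum to one.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .congeners import SECONDS_PER_YEAR
from .errors import DegenerateInputError, InvalidInputError

AIR_WATER_PROCESSES = ("volatilization", "absorption",
                       "wet_deposition", "dry_deposition")
SEDIMENT_WATER_PROCESSES = ("sediment_diffusion", "settling", "resuspension")
INTERFACE_PROCESSES = AIR_WATER_PROCESSES + SEDIMENT_WATER_PROCESSES

ROW_LABELS = {
    "volatilization": "Volatilization",
    "absorption": "Absorption",
    "wet_deposition": "Wet deposition",
    "dry_deposition": "Dry deposition",
    "sediment_diffusion": "Sedi/water diff.",
    "settling": "Settling",
    "resuspension": "Resuspension",
}


class BudgetTable:
    """Per-process, per-congener areal fluxes over one period.

    Wraps a DataFrame (rows = processes, columns = congeners) in
    ng m-2 per period (yearly for the annual table).  Extra rows beyond the
    interface processes (river loads, degradation, burial) are carried
    along but excluded from the sigma interface sums.
    """

    def __init__(self, frame: pd.DataFrame, period: str = "year"):
        missing = [p for p in INTERFACE_PROCESSES if p not in frame.index]
        if missing:
            raise InvalidInputError(f"budget table missing processes: {missing}")
        self.frame = frame.astype(float)
        self.period = period

    @classmethod
    def from_tsv(cls, path=None, period: str = "year") -> "BudgetTable":
        """Load a process-by-congener flux table (defaults to the packaged
        Thau reference annual fluxes)."""
        if path is None:
            path = resources.files("lagoonfate.data") / "thau_annual_fluxes.tsv"
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df, period=period)

    @property
    def congeners(self) -> list[str]:
        return list(self.frame.columns)

    def row(self, process: str) -> pd.Series:
        return self.frame.loc[process]

    def sigma_air_water(self) -> pd.Series:
        """Net air-water exchange per congener (volat + abs + wet + dry)."""
        return self.frame.loc[list(AIR_WATER_PROCESSES)].sum(axis=0)

    def sigma_sediment_water(self) -> pd.Series:
        """Net sediment-water exchange per congener (diff + settling + resusp)."""
        return self.frame.loc[list(SEDIMENT_WATER_PROCESSES)].sum(axis=0)

    def with_totals(self, decimals: int | None = 2) -> pd.DataFrame:
        """Presentation frame: labelled rows, sigma rows, congener-sum column."""
        rows = {}
        for p in AIR_WATER_PROCESSES:
            rows[ROW_LABELS[p]] = self.frame.loc[p]
        rows["Σ Air–water"] = self.sigma_air_water()
        for p in SEDIMENT_WATER_PROCESSES:
            rows[ROW_LABELS[p]] = self.frame.loc[p]
        rows["Σ Sediment–water"] = self.sigma_sediment_water()
        for p in self.frame.index:
            if p not in INTERFACE_PROCESSES:
                rows[p] = self.frame.loc[p]
        out = pd.DataFrame(rows).T
        out["Σ congeners"] = out.sum(axis=1)
        return out.round(decimals) if decimals is not None else out

    def to_tsv(self, path, decimals: int = 2) -> None:
        self.with_totals(decimals).to_csv(path, sep="\t")


def aggregate_fluxes(records: xr.Dataset, period: str = "year",
                     area: float | None = None):
    """Aggregate a binned flux-mass record into a budget.

    ``records`` is the dataset produced by ``RunResult.to_dataset()``
    (variable ``flux_mass`` in ng with dims time/box/congener/process).
    ``period="year"`` returns a :class:`BudgetTable` in ng m-2 yr-1
    (time-integral over the record, scaled to a 365-day year, divided by
    the total lagoon area); ``period="month"`` returns a DataFrame of
    monthly areal loads (ng m-2 month-1) whose sum over months equals the
    annual integral exactly.
    """
    if "flux_mass" not in records:
        raise InvalidInputError("records must contain 'flux_mass'")
    if area is None:
        area = float(records.attrs.get("total_area", 0.0)) or \
            float(records["box_area"].sum())
    mass = records["flux_mass"]
    if period == "year":
        total = mass.sum(dim=("time", "box")) / area  # ng m-2 over the record
        span = records.attrs.get("bin_seconds", None)
        if span is not None:
            duration = float(span) * records.sizes["time"]
            total = total * (SECONDS_PER_YEAR / duration)
        df = total.to_pandas()  # congener x process
        return BudgetTable(df.T, period="year")
    if period == "month":
        monthly = mass.sum(dim="box").groupby("time.month").sum(dim="time") / area
        # rows = calendar month, columns = (congener, process)
        return monthly.to_series().unstack("month").T
    raise InvalidInputError(f"unknown period {period!r}")


def net_interface_fluxes(table: BudgetTable) -> pd.DataFrame:
    """Sigma rows of the budget: net air-water and sediment-water exchange.

    Returns a DataFrame with rows ``air_water`` and ``sediment_water``, one
    column per congener plus a ``total`` column summed over congeners.
    """
    out = pd.DataFrame({
        "air_water": table.sigma_air_water(),
        "sediment_water": table.sigma_sediment_water(),
    }).T
    out["total"] = out.sum(axis=1)
    return out


def source_apportionment(table: BudgetTable,
                         river_loads: pd.Series | None = None) -> pd.DataFrame:
    """Positive-input source shares per congener (air / sediment / river).

    Only input fluxes count: for air the sum of absorption and wet and dry
    deposition, for sediments diffusion (clamped at zero when directed into
    the bed) plus resuspension.  ``river_loads`` are areal river inputs in
    the table's units; when None, a ``river_in`` row of the table is used
    if present, else zero.
    """
    clamp = lambda s: s.clip(lower=0.0)
    air = (clamp(table.row("absorption")) + clamp(table.row("wet_deposition"))
           + clamp(table.row("dry_deposition")))
    sed = clamp(table.row("sediment_diffusion")) + clamp(table.row("resuspension"))
    if river_loads is None:
        if "river_in" in table.frame.index:
            river_loads = table.row("river_in")
        else:
            river_loads = pd.Series(0.0, index=table.frame.columns)
    river = river_loads.reindex(table.frame.columns).fillna(0.0).clip(lower=0.0)
    total = air + sed + river
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise DegenerateInputError(f"no positive inputs for {bad}: shares undefined")
    out = pd.DataFrame({"share_air": air / total,
                        "share_sediment": sed / total,
                        "share_river": river / total})
    return out
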