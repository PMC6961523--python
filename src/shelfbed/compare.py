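"""Model-observation comparison harness.

Observations are small CSV tables with columns
``site, date, quantity, replicate, value`` (an optional ``source`` column
is carried through). Quantities are matched against model output columns
by name; per (quantity, date) the harness reports the model value at the
matching date, the replicate mean and range, the bias, and whether the
model falls inside the replicate range, plus per-quantity bias and RMSE
summaries.
"""

from __future__ import annotations

import pandas as pd

from .scenarios import OUTPUT_COLUMNS, OutputTables


class UnknownQuantityError(ValueError):
    pass


#: observation quantity name -> model output column (with units suffix)
QUANTITY_COLUMNS = {
    name: f"{name}_{unit}"
    for name, unit in OUTPUT_COLUMNS.items()
    if name not in ("ledger_residual",)
}

REQUIRED_OBS_COLUMNS = ("site", "date", "quantity", "replicate", "value")


def _model_series(model: OutputTables, quantity: str) -> pd.Series:
    if quantity not in QUANTITY_COLUMNS:
        raise UnknownQuantityError(
            f"unknown quantity {quantity!r}; supported: "
            f"{sorted(QUANTITY_COLUMNS)}"
        )
    daily = model.daily
    t0 = model.config.forcing.t_start
    dates = pd.Timestamp(t0) + pd.to_timedelta(daily["time_days"], unit="D")
    return pd.Series(daily[QUANTITY_COLUMNS[quantity]].to_numpy(), index=dates)


def compare(model: OutputTables, observations: pd.DataFrame) -> dict:
    """Score model output against replicate observations.

    Returns ``{"rows": per-(quantity, date) table, "summary": per-quantity
    bias/RMSE table}``. Observation dates with no exact model date match
    snap to the nearest model day.
    """
    missing = set(REQUIRED_OBS_COLUMNS) - set(observations.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])

    rows = []
    for (quantity, date), grp in obs.groupby(["quantity", "date"]):
        series = _model_series(model, quantity)
        idx = series.index.get_indexer([date], method="nearest")[0]
        model_value = float(series.iloc[idx])
        vals = grp["value"].astype(float)
        lo, hi = float(vals.min()), float(vals.max())
        mean = float(vals.mean())
        rows.append(
            {
                "quantity": quantity,
                "date": date,
                "n_replicates": len(vals),
                "obs_mean": mean,
                "obs_min": lo,
                "obs_max": hi,
                "model_value": model_value,
                "bias": model_value - mean,
                "within_range": bool(lo <= model_value <= hi),
            }
        )
    row_df = pd.DataFrame(rows)

    summaries = []
    for quantity, grp in row_df.groupby("quantity"):
        bias = grp["bias"]
        summaries.append(
            {
                "quantity": quantity,
                "n_dates": len(grp),
                "mean_bias": float(bias.mean()),
                "rmse": float((bias**2).mean() ** 0.5),
                "frac_within_range": float(grp["within_range"].mean()),
            }
        )
    return {"rows": row_df, "summary": pd.DataFrame(summaries)}
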