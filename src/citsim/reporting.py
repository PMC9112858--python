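"""Summary quantities and table builders.

Rates are expressed as events per 1000 person-years with log-normal Wald
confidence intervals; proportions as percentages by delivery type.  Display
rounding is half-up to two decimals, with full-precision values retained in
the CSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Z_95, ModelResult


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RateSummary:
    n_events: int
    person_years: float
    rate_per_1000: float  # full precision
    ci95: tuple[float, float] | None  # None when n_events == 0

    @property
    def display(self) -> str:
        r = round_half_up(self.rate_per_1000, 2)
        if self.ci95 is None:
            return f"{r:.2f}"
        lo, hi = (round_half_up(v, 2) for v in self.ci95)
        return f"{r:.2f} ({lo:.2f} to {hi:.2f})"


def rate_per_1000(n_events: int, person_years: float) -> RateSummary:
    """Events per 1000 person-years with a log-normal Wald 95% CI.

    CI = rate * exp(-+ 1.96/sqrt(n)); undefined when no events occurred.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    rate = 1000.0 * n_events / person_years
    if n_events == 0:
        return RateSummary(n_events, person_years, rate, None)
    half = Z_95 / math.sqrt(n_events)
    return RateSummary(n_events, person_years, rate,
                       (rate * math.exp(-half), rate * math.exp(half)))


def proportion(n: int, denom: int) -> float:
    """Percentage ``100 * n / denom`` (full precision; round for display)."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * n / denom


def _mask(n: int, mask_small: bool) -> str:
    return "<=5" if mask_small and 0 < n <= 5 else str(n)


def write_markdown_table(frame: pd.DataFrame, path: Path) -> None:
    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    Path(path).write_text("\n".join(lines) + "\n")


def births_by_year_table(cohort: pd.DataFrame,
                         mask_small: bool = False) -> pd.DataFrame:
    """Births by calendar year and delivery type, with a totals row."""
    tab = (cohort.groupby(["birth_year", "delivery_type"], observed=True)
           .size().unstack(fill_value=0))
    for col in ("caesarean", "vaginal"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["caesarean", "vaginal"]].sort_index()
    out = tab.reset_index().rename(columns={"birth_year": "year"})
    total = pd.DataFrame([{"year": "Total",
                           "caesarean": int(tab["caesarean"].sum()),
                           "vaginal": int(tab["vaginal"].sum())}])
    out = pd.concat([out, total], ignore_index=True)
    if mask_small:
        for col in ("caesarean", "vaginal"):
            out[col] = [_mask(int(v), True) for v in out[col]]
    return out


def outcome_table(rates: dict[str, RateSummary],
                  results: dict[str, ModelResult],
                  requested: list[str] | None = None) -> pd.DataFrame:
    """Per-outcome rate / IRR / CI / p table.

    Rare outcomes keep their counts but show a dash in the model columns;
    an outcome with no result is listed as absent rather than dropped.
    """
    outcomes = requested or sorted(set(rates) | set(results))
    rows = []
    for o in outcomes:
        r = rates.get(o)
        m = results.get(o)
        row = {"outcome": o}
        if r is None:
            row.update({"n_events": "absent", "person_years": "absent",
                        "rate_per_1000": "-"})
        else:
            row.update({
                "n_events": r.n_events,
                "person_years": round(r.person_years, 1),
                "rate_per_1000": r.display,
            })
        if m is None or m.rare_flag or m.effect is None:
            row.update({"irr": "-", "irr_ci95": "-", "p_value": "-"})
        else:
            lo, hi = m.ci95
            row.update({
                "irr": f"{m.effect:.2f}",
                "irr_ci95": f"{lo:.2f} to {hi:.2f}",
                "p_value": f"{m.p_value:.2g}",
            })
        rows.append(row)
    return pd.DataFrame(rows)


def maternal_table(deliveries: pd.DataFrame,
                   results: dict[str, ModelResult] | None = None
                   ) -> pd.DataFrame:
    """Counts and percentages of maternal outcomes by delivery type."""
    results = results or {}
    flags = [c for c in deliveries.columns if c.startswith("flag_")]
    n_cs = int((deliveries["delivery_type"] == "caesarean").sum())
    n_vd = int((deliveries["delivery_type"] == "vaginal").sum())
    rows = []
    for col in flags:
        name = col[len("flag_"):]
        cs = int(deliveries.loc[
            deliveries["delivery_type"] == "caesarean", col].sum())
        vd = int(deliveries.loc[
            deliveries["delivery_type"] == "vaginal", col].sum())
        m = results.get(name)
        row = {
            "outcome": name,
            "caesarean_n": cs,
            "caesarean_pct": round_half_up(proportion(cs, n_cs), 2)
            if n_cs else "-",
            "vaginal_n": vd,
            "vaginal_pct": round_half_up(proportion(vd, n_vd), 2)
            if n_vd else "-",
        }
        if m is None or m.rare_flag or m.effect is None:
            row.update({"irr": "-", "irr_ci95": "-", "p_value": "-"})
        else:
            lo, hi = m.ci95
            row.update({"irr": f"{m.effect:.2f}",
                        "irr_ci95": f"{lo:.2f} to {hi:.2f}",
                        "p_value": f"{m.p_value:.2g}"})
        rows.append(row)
    return pd.DataFrame(rows)


def build_tables(cohort: pd.DataFrame,
                 rates: dict[str, RateSummary],
                 results: dict[str, ModelResult],
                 out_dir,
                 maternal: pd.DataFrame | None = None,
                 maternal_results: dict[str, ModelResult] | None = None,
                 mask_small: bool = False) -> dict[str, Path]:
    """Write CSV + Markdown report tables; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    births = births_by_year_table(cohort, mask_small=mask_small)
    paths = (out_dir / "table1_births.csv", out_dir / "table1_births.md")
    births.to_csv(paths[0], index=False)
    write_markdown_table(births, paths[1])
    written["births"] = paths[0]

    # full-precision companion for round-tripping
    outcomes = outcome_table(rates, results)
    outcomes.to_csv(out_dir / "table2_outcomes.csv", index=False)
    write_markdown_table(outcomes, out_dir / "table2_outcomes.md")
    raw = pd.DataFrame([
        {"outcome": o, "n_events": r.n_events,
         "person_years": r.person_years, "rate_per_1000": r.rate_per_1000,
         "rate_ci_low": r.ci95[0] if r.ci95 else np.nan,
         "rate_ci_high": r.ci95[1] if r.ci95 else np.nan}
        for o, r in rates.items()])
    raw.to_csv(out_dir / "table2_outcomes_raw.csv", index=False)
    written["outcomes"] = out_dir / "table2_outcomes.csv"
    written["outcomes_raw"] = out_dir / "table2_outcomes_raw.csv"

    if maternal is not None:
        mat = maternal_table(maternal, maternal_results)
        mat.to_csv(out_dir / "table3_maternal.csv", index=False)
        write_markdown_table(mat, out_dir / "table3_maternal.md")
        written["maternal"] = out_dir / "table3_maternal.csv"
    return written
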