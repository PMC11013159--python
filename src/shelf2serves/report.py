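"""Render store reports: gauges against targets, trends, traffic-light colours.

Each selected indicator gets a speedometer-style gauge for the latest period
(green zone on the target-satisfying side, red on the violating side — the
orientation flips for the at-most Unhealthy Foods target) and a line or bar
trend chart over the requested window with optional comparator overlays
(all-store average, guideline target, user-set target).  Healthiness tiers
use a colour-blind-safe traffic-light palette.  Output is a self-contained
HTML document with charts embedded as SVG plus a JSON machine payload; with a
fixed seed upstream the bytes are reproducible (no timestamps unless stamped).
"""

from __future__ import annotations

import html as _html
import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .comparators import COMPARATOR_KINDS, all_store_average, trend_series
from .indicators import IndicatorSet, compute_indicator_sets, indicator_label
from .reference_data import ClassificationScheme, HealthinessTier, default_scheme
from .targets import Direction, Target, TargetSet, default_targets

#: Okabe-Ito colour-blind-safe traffic lights.
TRAFFIC_LIGHT_HEX: dict[HealthinessTier, str] = {
    HealthinessTier.BEST: "#009E73",          # green
    HealthinessTier.LESS_HEALTHY: "#E69F00",  # amber
    HealthinessTier.UNHEALTHY: "#D55E00",     # red
}
_GREEN, _RED, _GREY = "#009E73", "#D55E00", "#BBBBBB"

# deterministic SVG ids so identical inputs give identical bytes
matplotlib.rcParams["svg.hashsalt"] = "shelf2serves"


def traffic_light(tier: HealthinessTier) -> str:
    """Hex colour for a healthiness tier (green / amber / red)."""
    try:
        return TRAFFIC_LIGHT_HEX[HealthinessTier(tier)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown healthiness tier {tier!r}") from exc


def meets_target(value: float, target: Target) -> Optional[bool]:
    """Whether a value satisfies a directed target; boundary inclusive.

    Returns None (rendered grey / "no data") for an undefined value.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if target.direction is Direction.AT_LEAST:
        return value >= target.value
    return value <= target.value


class ReportSpec(BaseModel):
    """User customisation of a store report."""

    store_id: str
    window: int = Field(default=6, ge=1, description="periods to display")
    period_unit: str = "month"
    comparators: list[str] = Field(default_factory=lambda: ["guideline-target"])
    selected_indicators: list[str] = Field(
        default_factory=lambda: ["fruit", "vegetables", "breads_cereals",
                                 "meat_fish_eggs", "dairy", "unhealthy_foods"]
    )
    user_targets: Optional[TargetSet] = None
    chart: str = Field(default="line", pattern="^(line|bar)$")

    @model_validator(mode="after")
    def _check(self) -> "ReportSpec":
        if not self.selected_indicators:
            raise ValueError("selected_indicators must be non-empty")
        unknown = [c for c in self.comparators if c not in COMPARATOR_KINDS]
        if unknown:
            raise ValueError(f"unknown comparators {unknown}; valid: {list(COMPARATOR_KINDS)}")
        if self.user_targets is not None and "user-target" not in self.comparators:
            self.user_targets = None  # only used when listed in comparators
        return self


@dataclass
class GaugePanel:
    """One speedometer panel: current value against a directed target."""

    indicator_key: str
    value: float  # NaN when undefined
    target: Target
    gauge_max: float

    @property
    def status(self) -> Optional[bool]:
        return meets_target(self.value, self.target)


def build_gauge_panel(indicator_key: str, value: float, target: Target) -> GaugePanel:
    observed = 0.0 if (value is None or math.isnan(value)) else value
    gauge_max = max(2.0 * target.value, observed, 1.0)
    return GaugePanel(indicator_key, value, target, gauge_max)


def _render_gauge_svg(panel: GaugePanel, label: str) -> str:
    """Half-dial gauge: green zone on the target-satisfying side."""
    fig, ax = plt.subplots(figsize=(3.2, 2.1))
    ax.set_aspect("equal")
    ax.axis("off")
    gmax = panel.gauge_max
    frac = panel.target.value / gmax  # 0..1 along the dial
    # dial runs 180deg (value 0) to 0deg (gauge_max)
    split = 180.0 - 180.0 * frac
    from matplotlib.patches import Wedge
    if panel.target.direction is Direction.AT_LEAST:
        below, above = _RED, _GREEN  # too few serves is the problem
    else:
        below, above = _GREEN, _RED  # at-most: excess is the problem
    ax.add_patch(Wedge((0, 0), 1.0, split, 180.0, width=0.32, facecolor=below, edgecolor="white"))
    ax.add_patch(Wedge((0, 0), 1.0, 0.0, split, width=0.32, facecolor=above, edgecolor="white"))
    undefined = panel.value is None or math.isnan(panel.value)
    if not undefined:
        vfrac = min(max(panel.value / gmax, 0.0), 1.0)
        ang = math.radians(180.0 - 180.0 * vfrac)
        ax.plot([0, 0.88 * math.cos(ang)], [0, 0.88 * math.sin(ang)], color="#222222", lw=2.5)
        ax.add_patch(plt.Circle((0, 0), 0.05, color="#222222"))
        centre_text = f"{panel.value:.1f}"
    else:
        centre_text = "no data"
    sign = "≥" if panel.target.direction is Direction.AT_LEAST else "≤"
    ax.text(0, -0.28, centre_text, ha="center", fontsize=13, fontweight="bold")
    ax.text(0, -0.5, f"target {sign} {panel.target.value:g}", ha="center", fontsize=8)
    ax.set_title(label, fontsize=10)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-0.6, 1.15)
    return _fig_to_svg(fig)


def _render_trend_svg(
    label: str,
    series: pd.Series,
    chart: str,
    overlays: dict[str, pd.Series],
    unit_label: str,
) -> str:
    fig, ax = plt.subplots(figsize=(4.6, 2.4))
    x = range(len(series))
    if chart == "bar":
        ax.bar(x, series.values, color="#56B4E9", label="This store")
    else:
        ax.plot(x, series.values, marker="o", color="#0072B2", label="This store")
    styles = {"guideline-target": (_GREEN, "--"), "user-target": ("#CC79A7", ":"),
              "all-store-average": ("#999999", "-.")}
    for name, ov in overlays.items():
        colour, ls = styles.get(name, ("#000000", "-"))
        ax.plot(x, ov.reindex(series.index).values, ls, color=colour, label=name)
    ax.set_xticks(list(x))
    ax.set_xticklabels(series.index, fontsize=7, rotation=45, ha="right")
    ax.set_ylabel("serves/person/day", fontsize=8)
    ax.set_title(f"{label} — {unit_label}", fontsize=10)
    ax.legend(fontsize=6, loc="best")
    ax.tick_params(labelsize=7)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


SERVE_GUIDE_MD = """\
### What is a serve?

| Food group | One serve is about |
|---|---|
| Fruit | 150 g fresh fruit (1 medium apple) |
| Vegetables | 75 g cooked or raw vegetables (half a cup) |
| Breads and Cereals | 1 slice of bread or half a cup of cooked rice |
| Meat, Fish and Eggs | 65 g cooked lean meat, 100 g fish, or 2 eggs |
| Dairy | 1 cup (250 mL) of milk or 2 slices (40 g) of cheese |
| Unhealthy Foods | about 600 kJ — e.g. 375 mL of soft drink or a small chocolate bar |

### Frequently asked questions

**Why serves per person per day?** Sales are scaled to 8.9 MJ of energy —
the average daily energy a person needs — so stores of different sizes and
months of different lengths can be compared to the dietary guidelines.

**Why don't hot chips count as vegetables?** Unhealthy (discretionary) foods
never count towards the five food groups in these reports, so the healthy
food groups only reflect genuinely healthy purchases.

**What do the colours mean?** Green = Best Choice, amber = Less Healthy
Choice, red = Unhealthy Foods. On a gauge, green means the store is on the
healthy side of the target.
"""


def _md_to_html(md: str) -> str:
    """Minimal markdown rendering (headings, tables, bold) for the guide."""
    out, in_table = [], False
    for line in md.splitlines():
        if line.startswith("|"):
            cells = [c.strip() for c in line.strip("|").split("|")]
            if all(set(c) <= {"-"} for c in cells):
                continue
            tag = "th" if not in_table else "td"
            if not in_table:
                out.append("<table>")
                in_table = True
            out.append("<tr>" + "".join(f"<{tag}>{_html.escape(c)}</{tag}>" for c in cells) + "</tr>")
            continue
        if in_table:
            out.append("</table>")
            in_table = False
        if line.startswith("### "):
            out.append(f"<h3>{_html.escape(line[4:])}</h3>")
        elif line.strip():
            txt = _html.escape(line)
            while "**" in txt:
                txt = txt.replace("**", "<strong>", 1).replace("**", "</strong>", 1)
            out.append(f"<p>{txt}</p>")
    if in_table:
        out.append("</table>")
    return "\n".join(out)


def build_report(
    spec: ReportSpec,
    quantified: pd.DataFrame,
    targets: TargetSet | None = None,
    scheme: ClassificationScheme | None = None,
    stamp: str | None = None,
    **indicator_kwargs,
) -> tuple[str, dict]:
    """Build the store report.

    Returns (HTML document, JSON-able machine payload).  The payload carries
    indicator values, targets, comparator series and per-indicator statuses —
    everything a hosting portal would need without re-parsing the HTML.
    """
    targets = targets or default_targets()
    scheme = scheme or default_scheme()
    user_targets = spec.user_targets

    all_sets = compute_indicator_sets(quantified, period_unit=spec.period_unit, **indicator_kwargs)
    sections, payload_ind = [], {}
    for key in spec.selected_indicators:
        label = indicator_label(key, scheme)
        series, truncated = trend_series(
            quantified, spec.store_id, key, spec.window, spec.period_unit, **indicator_kwargs
        )
        if len(series) == 0:
            sections.append(
                f'<section class="indicator"><h2>{_html.escape(label)}</h2>'
                f'<p class="nodata">No data for this store in the selected window.</p></section>'
            )
            payload_ind[key] = {"periods": [], "values": [], "status": None}
            continue
        latest_period = series.index[-1]
        latest = float(series.iloc[-1])

        target = targets.target_for(key)
        overlays: dict[str, pd.Series] = {}
        if "guideline-target" in spec.comparators and target is not None:
            overlays["guideline-target"] = pd.Series(target.value, index=series.index)
        if "user-target" in spec.comparators and user_targets is not None:
            ut = user_targets.target_for(key)
            if ut is not None:
                overlays["user-target"] = pd.Series(ut.value, index=series.index)
        avg_note = ""
        if "all-store-average" in spec.comparators:
            avg = {p: all_store_average(all_sets, p, key) for p in series.index}
            overlays["all-store-average"] = pd.Series({p: a.value for p, a in avg.items()})
            ns = {a.n_stores for a in avg.values() if a.n_stores}
            if ns:
                avg_note = f'<p class="note">All-store average over n={max(ns)} stores.</p>'

        gauge_svg = ""
        status = None
        if target is not None:
            panel = build_gauge_panel(key, latest, target)
            status = panel.status
            gauge_svg = _render_gauge_svg(panel, f"{label} — {latest_period}")
        trend_svg = _render_trend_svg(
            label, series, spec.chart, overlays,
            "last %d %ss" % (len(series), spec.period_unit),
        )
        status_txt = {True: "Meeting target", False: "Not meeting target", None: "No target"}[status]
        status_cls = {True: "ok", False: "bad", None: "none"}[status]
        note = "<p class='note'>Fewer periods available than requested.</p>" if truncated else ""
        sections.append(
            f'<section class="indicator"><h2>{_html.escape(label)}</h2>'
            f'<p class="status {status_cls}">{status_txt}</p>'
            f'<div class="charts">{gauge_svg}{trend_svg}</div>{avg_note}{note}</section>'
        )
        payload_ind[key] = {
            "periods": list(series.index),
            "values": [None if math.isnan(v) else float(v) for v in series.values],
            "latest_period": latest_period,
            "latest_value": None if math.isnan(latest) else latest,
            "target": None if target is None else {"value": target.value, "direction": target.direction.value},
            "comparators": {
                name: [None if math.isnan(v) else float(v) for v in ov.values]
                for name, ov in overlays.items()
            },
            "status": status,
        }

    tier_legend = "".join(
        f'<span class="tier" style="background:{TRAFFIC_LIGHT_HEX[t]}">{t.value}</span>'
        for t in HealthinessTier
    )
    stamp_html = f"<p class='stamp'>Generated {_html.escape(stamp)}</p>" if stamp else ""
    html_doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>Store report — {_html.escape(spec.store_id)}</title>
<style>
body {{ font-family: sans-serif; max-width: 900px; margin: 2em auto; color: #222; }}
section.indicator {{ border: 1px solid #ddd; border-radius: 8px; padding: 0.8em 1.2em; margin: 1em 0; }}
.charts {{ display: flex; flex-wrap: wrap; align-items: center; gap: 1em; }}
.status.ok {{ color: {_GREEN}; font-weight: bold; }}
.status.bad {{ color: {_RED}; font-weight: bold; }}
.status.none {{ color: #666; }}
.nodata {{ color: #666; font-style: italic; }}
.note, .stamp {{ color: #888; font-size: 0.8em; }}
.tier {{ color: white; padding: 0.2em 0.6em; border-radius: 4px; margin-right: 0.5em; font-size: 0.85em; }}
table {{ border-collapse: collapse; }} td, th {{ border: 1px solid #ccc; padding: 0.3em 0.7em; font-size: 0.9em; }}
</style></head><body>
<h1>Healthy food sales report — {_html.escape(spec.store_id)}</h1>
<p>Serves of each food group sold per person per day, scaled to a daily energy
of 8.9&nbsp;MJ, compared with population-weighted dietary guideline targets.</p>
<p>{tier_legend}</p>
{stamp_html}
{''.join(sections)}
<footer>{_md_to_html(SERVE_GUIDE_MD)}</footer>
</body></html>
"""
    payload = {
        "store_id": spec.store_id,
        "period_unit": spec.period_unit,
        "window": spec.window,
        "reference_energy_kj": targets.reference_energy,
        "indicators": payload_ind,
    }
    return html_doc, payload


def write_report(html_doc: str, payload: dict, out_dir: str | Path, store_id: str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    html_path = out / f"report_{store_id}.html"
    html_path.write_text(html_doc, encoding="utf-8")
    (out / f"report_{store_id}.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return html_path
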