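"""Boron uptake and biodistribution analysis.

Covers the two measurement arms of a BPA boron-delivery study:

* in vitro — ICP-AES boron masses in cell lysates, normalised to
  μg ¹⁰B per 10⁹ cells and compared across BPA exposure levels and cell
  lines with two-sample t-tests;
* in vivo — organ boron concentrations (μg ¹⁰B/g) at fixed times after
  intravenous BPA, summarised per (tissue, time) as mean ± SD, with the
  tumour-to-normal ratios (T/SC, T/Bl, Bl/SC) that drive the choice of
  irradiation time.

Ratio conventions. Raw mode computes ratios from full-precision means.
Table mode reproduces a printed table: means are first rounded half-up to
one decimal and the ratio of rounded means is rounded again — the
convention under which most printed ratio cells are exactly recoverable.
Cells that cannot be recovered this way (they were evidently computed from
unrounded source data) are reported as reconstruction mismatches rather
than errors; see :func:`compare_printed_ratios`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._rounding import round_half_up

__all__ = [
    "TISSUE_TUMOR",
    "TISSUE_SPINAL_CORD",
    "TISSUE_BLOOD",
    "TISSUE_BRAIN",
    "CellUptakeRecord",
    "BoronMeasurement",
    "TimecourseSummary",
    "RatioSet",
    "cellular_boron_concentration",
    "summarize_timecourse",
    "tissue_ratios",
    "compare_printed_ratios",
    "select_irradiation_time",
    "concentration_dependence_test",
    "retention_summary",
]

TISSUE_TUMOR = "tumor"
TISSUE_SPINAL_CORD = "spinal cord"
TISSUE_BLOOD = "blood"
TISSUE_BRAIN = "brain"


@dataclass(frozen=True)
class CellUptakeRecord:
    """One ICP-AES measurement of a cell-lysate boron mass.

    ``washout`` marks the retention arm of the protocol (boron-free
    incubation after exposure); retention records are excluded from the
    concentration-dependence comparisons and only summarised.
    """

    cell_line: str
    exposure_conc: float  # μg B/mL in the exposure medium
    exposure_h: float  # hours of exposure
    boron_mass: float  # μg ¹⁰B in the lysate
    cell_count: int  # cells in the lysate
    replicate: int
    washout: bool = False

    def __post_init__(self) -> None:
        if self.cell_count <= 0:
            raise ValueError(f"cell_count must be > 0, got {self.cell_count!r}")
        if self.boron_mass < 0 or not math.isfinite(self.boron_mass):
            raise ValueError(f"boron_mass must be finite and >= 0, got {self.boron_mass!r}")
        if self.exposure_conc < 0:
            raise ValueError(f"exposure_conc must be >= 0, got {self.exposure_conc!r}")

    @property
    def concentration(self) -> float:
        """μg ¹⁰B per 10⁹ cells."""
        return cellular_boron_concentration(self.boron_mass, self.cell_count)


@dataclass(frozen=True)
class BoronMeasurement:
    """One in vivo organ boron concentration observation."""

    subject_id: str
    tissue: str
    time_h: float  # hours after end of BPA infusion
    conc: float  # μg ¹⁰B/g
    model: str = ""  # tumour model label (F98 | 9L), optional

    def __post_init__(self) -> None:
        if self.conc < 0 or not math.isfinite(self.conc):
            raise ValueError(f"conc must be finite and >= 0, got {self.conc!r}")
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h!r}")


@dataclass(frozen=True)
class TimecourseSummary:
    """Mean ± SD of one tissue at one sampling time."""

    tissue: str
    time_h: float
    n: int
    mean: float
    sd: float
    sd_degenerate: bool = False  # True when n == 1 and sd is reported as 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class RatioSet:
    """Tumour-to-normal concentration ratios at one time point.

    ``t_sc``, ``t_bl`` and ``bl_sc`` hold the values at the precision of
    the mode that produced them (full precision in raw mode, table
    convention in table mode); :meth:`rounded` renders one-decimal values
    for display.
    """

    time_h: float
    t_sc: float  # tumour / spinal cord
    t_bl: float  # tumour / blood
    bl_sc: float  # blood / spinal cord

    def rounded(self, ndigits: int = 1) -> "RatioSet":
        return RatioSet(
            time_h=self.time_h,
            t_sc=round_half_up(self.t_sc, ndigits),
            t_bl=round_half_up(self.t_bl, ndigits),
            bl_sc=round_half_up(self.bl_sc, ndigits),
        )


def cellular_boron_concentration(boron_mass: float, cell_count: int) -> float:
    """Normalise a lysate boron mass to μg ¹⁰B per 10⁹ cells."""
    if cell_count <= 0:
        raise ValueError(f"cell_count must be > 0, got {cell_count!r}")
    if boron_mass < 0:
        raise ValueError(f"boron_mass must be >= 0, got {boron_mass!r}")
    return boron_mass / cell_count * 1e9


def summarize_timecourse(
    measurements: list[BoronMeasurement],
) -> list[TimecourseSummary]:
    """Per-(tissue, time) n, mean and sample SD, ordered by tissue then time.

    The SD uses the n−1 denominator; a single observation yields sd = 0
    flagged as degenerate.
    """
    if not measurements:
        raise ValueError("summarize_timecourse requires at least one measurement")
    df = pd.DataFrame(
        {
            "tissue": [m.tissue for m in measurements],
            "time_h": [m.time_h for m in measurements],
            "conc": [m.conc for m in measurements],
        }
    )
    out: list[TimecourseSummary] = []
    for (tissue, time_h), group in df.groupby(["tissue", "time_h"], sort=True):
        n = len(group)
        sd = float(group["conc"].std(ddof=1)) if n > 1 else 0.0
        out.append(
            TimecourseSummary(
                tissue=str(tissue),
                time_h=float(time_h),
                n=n,
                mean=float(group["conc"].mean()),
                sd=sd,
                sd_degenerate=n == 1,
            )
        )
    return out


def _means_at(summaries: list[TimecourseSummary], time_h: float) -> dict[str, float]:
    return {
        s.tissue: s.mean
        for s in summaries
        if math.isclose(s.time_h, time_h, rel_tol=0, abs_tol=1e-9)
    }


def tissue_ratios(
    summaries: list[TimecourseSummary], time_h: float, mode: str = "raw"
) -> RatioSet:
    """T/SC, T/Bl and Bl/SC ratios at one sampling time.

    ``mode="raw"`` divides full-precision means. ``mode="table"`` applies
    the printed-table convention: round means half-up to one decimal,
    divide, round the ratio to one decimal.
    """
    if mode not in ("raw", "table"):
        raise ValueError(f"mode must be 'raw' or 'table', got {mode!r}")
    means = _means_at(summaries, time_h)
    missing = [
        t for t in (TISSUE_TUMOR, TISSUE_SPINAL_CORD, TISSUE_BLOOD) if t not in means
    ]
    if missing:
        raise ValueError(f"no summary for {missing} at time {time_h} h")
    tumor = means[TISSUE_TUMOR]
    cord = means[TISSUE_SPINAL_CORD]
    blood = means[TISSUE_BLOOD]
    if mode == "table":
        tumor, cord, blood = (round_half_up(v, 1) for v in (tumor, cord, blood))
    if cord <= 0 or blood <= 0:
        raise ValueError(
            f"zero denominator at {time_h} h: spinal cord {cord}, blood {blood}"
        )
    ratios = RatioSet(
        time_h=time_h, t_sc=tumor / cord, t_bl=tumor / blood, bl_sc=blood / cord
    )
    return ratios.rounded(1) if mode == "table" else ratios


def compare_printed_ratios(
    summaries: list[TimecourseSummary],
    printed: dict[float, tuple[float, float, float]],
) -> pd.DataFrame:
    """Check which printed ratio cells are recoverable in table mode.

    ``printed`` maps time (h) to the printed (T/SC, T/Bl, Bl/SC) triple.
    Returns one row per cell with columns ``time_h``, ``ratio``,
    ``reconstructed``, ``printed`` and ``mismatch`` — mismatched cells are
    those the table convention cannot reproduce from the rounded means,
    i.e. cells evidently computed from unrounded source data.
    """
    rows = []
    for time_h, (p_tsc, p_tbl, p_blsc) in sorted(printed.items()):
        r = tissue_ratios(summaries, time_h, mode="table")
        for name, recon, printed_value in (
            ("T/SC", r.t_sc, p_tsc),
            ("T/Bl", r.t_bl, p_tbl),
            ("Bl/SC", r.bl_sc, p_blsc),
        ):
            rows.append(
                {
                    "time_h": time_h,
                    "ratio": name,
                    "reconstructed": recon,
                    "printed": printed_value,
                    "mismatch": not math.isclose(recon, printed_value, abs_tol=1e-9),
                }
            )
    return pd.DataFrame(rows)


def select_irradiation_time(summaries: list[TimecourseSummary]) -> float:
    """Choose the irradiation time from the organ time-course summaries.

    The decision inputs are absolute tumour boron first, then the
    tumour-to-spinal-cord and tumour-to-blood ratios; the time maximising
    this lexicographic criterion wins, with ties broken by the earliest
    time (earlier irradiation is logistically preferable at equal uptake).
    """
    times = sorted({s.time_h for s in summaries})
    candidates = []
    for t in times:
        means = _means_at(summaries, t)
        if all(
            tissue in means and means[tissue] > 0
            for tissue in (TISSUE_TUMOR, TISSUE_SPINAL_CORD, TISSUE_BLOOD)
        ):
            r = tissue_ratios(summaries, t, mode="raw")
            candidates.append((t, means[TISSUE_TUMOR], r.t_sc, r.t_bl))
    if not candidates:
        raise ValueError("no time point has complete tumor/spinal cord/blood summaries")
    best = min(candidates, key=lambda c: (-c[1], -c[2], -c[3], c[0]))
    return best[0]


def concentration_dependence_test(
    uptake: list[CellUptakeRecord], equal_var: bool = True
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Pairwise t-tests of cellular uptake across exposure levels and lines.

    For every pair of exposure levels within a cell line, and every pair of
    cell lines at a fixed level, a two-sided two-sample t-test is run on
    the normalised concentrations (pooled-variance Student's t by default,
    Welch with ``equal_var=False``). Washout (retention) records are
    excluded. Returns the comparison table and, per cell line, whether the
    level means increase monotonically with exposure concentration.
    """
    groups: dict[tuple[str, float], list[float]] = {}
    for rec in uptake:
        if rec.washout:
            continue
        groups.setdefault((rec.cell_line, rec.exposure_conc), []).append(
            rec.concentration
        )
    if not groups:
        raise ValueError("no non-washout uptake records")
    for key, values in groups.items():
        if len(values) < 2:
            raise ValueError(
                f"group {key} has {len(values)} replicate(s); need at least 2"
            )

    rows = []
    lines = sorted({line for line, _ in groups})
    for line in lines:
        levels = sorted(level for ln, level in groups if ln == line)
        for lo, hi in itertools.combinations(levels, 2):
            a, b = groups[(line, lo)], groups[(line, hi)]
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(
                {
                    "comparison": "level",
                    "cell_line": line,
                    "group_a": lo,
                    "group_b": hi,
                    "n_a": len(a),
                    "n_b": len(b),
                    "mean_a": sum(a) / len(a),
                    "mean_b": sum(b) / len(b),
                    "t": float(t),
                    "p": float(p),
                }
            )
    levels_all = sorted({level for _, level in groups})
    for level in levels_all:
        present = [line for line in lines if (line, level) in groups]
        for la, lb in itertools.combinations(present, 2):
            a, b = groups[(la, level)], groups[(lb, level)]
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(
                {
                    "comparison": "cell_line",
                    "cell_line": f"{la} vs {lb}",
                    "group_a": level,
                    "group_b": level,
                    "n_a": len(a),
                    "n_b": len(b),
                    "mean_a": sum(a) / len(a),
                    "mean_b": sum(b) / len(b),
                    "t": float(t),
                    "p": float(p),
                }
            )

    monotone = {}
    for line in lines:
        levels = sorted(level for ln, level in groups if ln == line)
        means = [sum(groups[(line, lv)]) / len(groups[(line, lv)]) for lv in levels]
        monotone[line] = all(m1 < m2 for m1, m2 in zip(means, means[1:]))
    return pd.DataFrame(rows), monotone


def retention_summary(uptake: list[CellUptakeRecord]) -> pd.DataFrame:
    """Mean ± SD of retained boron per (cell line, level) for washout records."""
    rows = [
        {
            "cell_line": r.cell_line,
            "exposure_conc": r.exposure_conc,
            "concentration": r.concentration,
        }
        for r in uptake
        if r.washout
    ]
    if not rows:
        return pd.DataFrame(
            columns=["cell_line", "exposure_conc", "n", "mean", "sd"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["cell_line", "exposure_conc"])["concentration"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return out
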