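"""Pipeline orchestration: bind the analysis stages into one reproducible run.

Stage order follows the study logic: cellular uptake → organ
biodistribution and irradiation-time selection → dosimetry → survival and
locomotor efficacy. Each run emits tab-separated report tables (uptake
comparisons, the organ time-course/ratio table, the dose table, the
survival table), Kaplan–Meier curve points, BBB group means with the
MANOVA verdict, and a JSON manifest with input checksums so a run can be
audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from ._rounding import round_half_up
from .biodistribution import (
    TISSUE_SPINAL_CORD,
    TISSUE_TUMOR,
    concentration_dependence_test,
    select_irradiation_time,
    summarize_timecourse,
    tissue_ratios,
)
from .dosimetry import (
    CBE_NORMAL_CORD,
    CBE_TUMOR,
    DEFAULT_NITROGEN_WT_PCT,
    RBE_HYDROGEN,
    RBE_NITROGEN,
    NeutronField,
    RadiobiologicalWeights,
    TissueComposition,
    build_dose_report,
)
from .efficacy import (
    bbb_group_compare,
    format_p,
    km_estimate,
    prepare_bbb_matrix,
    survival_summary,
)

__all__ = ["DosimetrySettings", "PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("bnct")

PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class DosimetrySettings:
    """Neutron field and weighting settings forwarded to the dose stage."""

    flux: float | None = 9.4e8  # n/cm²/s
    duration_s: float | None = 1200.0  # 20 min irradiation
    thermal_fluence: float | None = None  # n/cm²; overrides flux × duration
    d_h: float = 0.0  # measured hydrogen-recoil dose, Gy
    d_gamma: float = 0.0  # measured photon dose, Gy
    nitrogen_wt_pct: float = DEFAULT_NITROGEN_WT_PCT
    cbe_tumor: float = CBE_TUMOR
    cbe_normal: float = CBE_NORMAL_CORD
    rbe_n: float = RBE_NITROGEN
    rbe_h: float = RBE_HYDROGEN

    def neutron_field(self) -> NeutronField:
        return NeutronField(
            thermal_fluence=self.thermal_fluence,
            flux=self.flux,
            duration=self.duration_s,
            measured_dh=self.d_h,
            measured_dgamma=self.d_gamma,
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "DosimetrySettings":
        nf = raw.get("neutron_field", {})
        w = raw.get("weights", {})
        return cls(
            flux=nf.get("flux"),
            duration_s=nf.get("duration_s"),
            thermal_fluence=nf.get("thermal_fluence"),
            d_h=float(nf.get("d_h", 0.0)),
            d_gamma=float(nf.get("d_gamma", 0.0)),
            nitrogen_wt_pct=float(
                raw.get("nitrogen_wt_pct", DEFAULT_NITROGEN_WT_PCT)
            ),
            cbe_tumor=float(w.get("cbe_tumor", CBE_TUMOR)),
            cbe_normal=float(w.get("cbe_normal", CBE_NORMAL_CORD)),
            rbe_n=float(w.get("rbe_n", RBE_NITROGEN)),
            rbe_h=float(w.get("rbe_h", RBE_HYDROGEN)),
        )


@dataclass(frozen=True)
class PipelineConfig:
    uptake_csv: Path
    biodistribution_csv: Path
    animals_csv: Path
    outdir: Path
    reference_group: str = "untreated"
    irradiation_start_day: int = 7
    dosimetry: DosimetrySettings = field(default_factory=DosimetrySettings)
    skip_invalid: bool = False

    @classmethod
    def from_dict(cls, raw: dict, outdir: str | Path) -> "PipelineConfig":
        return cls(
            uptake_csv=Path(raw["uptake_csv"]),
            biodistribution_csv=Path(raw["biodistribution_csv"]),
            animals_csv=Path(raw["animals_csv"]),
            outdir=Path(outdir),
            reference_group=raw.get("reference_group", "untreated"),
            irradiation_start_day=int(raw.get("irradiation_start_day", 7)),
            dosimetry=DosimetrySettings.from_dict(raw.get("dosimetry", {})),
            skip_invalid=bool(raw.get("skip_invalid", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, outdir)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    inputs: dict[str, str]
    stages: dict[str, str]
    started: str
    finished: str

    def write(self, path: Path) -> None:
        """Atomic write: rendered to a temp file, then renamed in place."""
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    raw = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode("utf-8")
    return hashlib.sha256(raw).hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _fmt(x: float | None, ndigits: int = 1) -> str:
    if x is None:
        return "-"
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):
        return "NA"  # undefined (e.g. median never reached under censoring)
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def _stage_uptake(config: PipelineConfig) -> None:
    records = _io.read_uptake(config.uptake_csv, config.skip_invalid).records
    logger.info("uptake: %d records", len(records))
    table, monotone = concentration_dependence_test(records)
    rows = [
        [
            r["comparison"],
            r["cell_line"],
            r["group_a"],
            r["group_b"],
            r["n_a"],
            r["n_b"],
            _fmt(r["mean_a"]),
            _fmt(r["mean_b"]),
            f"{r['t']:.3f}",
            format_p(r["p"]),
        ]
        for r in table.to_dict("records")
    ]
    for line, mono in sorted(monotone.items()):
        rows.append(["monotone_increase", line, "-", "-", "-", "-", "-", "-", "-", str(mono)])
    _write_tsv(
        config.outdir / "uptake_report.tsv",
        ["comparison", "cell_line", "group_a", "group_b", "n_a", "n_b",
         "mean_a", "mean_b", "t", "p"],
        rows,
    )


def _stage_biodistribution(config: PipelineConfig) -> float:
    records = _io.read_biodistribution(
        config.biodistribution_csv, config.skip_invalid
    ).records
    logger.info("biodistribution: %d measurements", len(records))
    summaries = summarize_timecourse(records)
    times = sorted({s.time_h for s in summaries})
    tissues = sorted({s.tissue for s in summaries})
    header = ["time_h", "n"]
    for tissue in tissues:
        header += [f"{tissue.replace(' ', '_')}_mean", f"{tissue.replace(' ', '_')}_sd"]
    header += ["T_SC", "T_Bl", "Bl_SC"]
    rows = []
    for t in times:
        at_t = {s.tissue: s for s in summaries if s.time_h == t}
        n = max(s.n for s in at_t.values())
        row: list = [f"{t:g}", n]
        for tissue in tissues:
            s = at_t.get(tissue)
            row += [_fmt(s.mean) if s else "-", _fmt(s.sd) if s else "-"]
        ratios = tissue_ratios(summaries, t, mode="raw").rounded(1)
        row += [f"{ratios.t_sc:.1f}", f"{ratios.t_bl:.1f}", f"{ratios.bl_sc:.1f}"]
        rows.append(row)
    _write_tsv(config.outdir / "table2.tsv", header, rows)

    selected = select_irradiation_time(summaries)
    logger.info("irradiation time selected: %g h", selected)
    with open(config.outdir / "irradiation_time.txt", "w", encoding="utf-8") as fh:
        fh.write(f"{selected:g}\n")
    return selected


def _stage_dose(config: PipelineConfig, selected_time: float) -> None:
    records = _io.read_biodistribution(
        config.biodistribution_csv, config.skip_invalid
    ).records
    summaries = summarize_timecourse(records)
    means = {
        s.tissue: s.mean for s in summaries if s.time_h == selected_time
    }
    settings = config.dosimetry
    neutron_field = settings.neutron_field()
    tissue_weights = {
        TISSUE_TUMOR: RadiobiologicalWeights(
            settings.cbe_tumor, settings.rbe_n, settings.rbe_h
        ),
        TISSUE_SPINAL_CORD: RadiobiologicalWeights(
            settings.cbe_normal, settings.rbe_n, settings.rbe_h
        ),
    }
    rows = []
    for group, with_boron in (("neutron-only", False), ("BNCT", True)):
        for tissue in (TISSUE_SPINAL_CORD, TISSUE_TUMOR):
            if tissue not in means:
                continue
            composition = TissueComposition(
                name=tissue,
                boron_conc=means[tissue] if with_boron else 0.0,
                nitrogen_wt_pct=settings.nitrogen_wt_pct,
            )
            report = build_dose_report(
                composition, tissue_weights[tissue], neutron_field
            )
            c = report.components
            rows.append(
                [
                    group,
                    tissue,
                    f"{c.d_b:.4f}",
                    f"{c.d_n:.4f}",
                    f"{c.d_h:.4f}",
                    f"{c.d_gamma:.4f}",
                    _fmt(report.absorbed),
                    _fmt(report.photon_equivalent),
                ]
            )
    _write_tsv(
        config.outdir / "table4.tsv",
        ["group", "tissue", "D_B", "D_N", "D_H", "D_gamma",
         "absorbed_Gy", "photon_eq_GyEq"],
        rows,
    )


def _stage_efficacy(config: PipelineConfig) -> None:
    records = _io.read_animals(config.animals_csv, config.skip_invalid).records
    logger.info("efficacy: %d animals", len(records))
    summaries = survival_summary(records, config.reference_group)
    _write_tsv(
        config.outdir / "table3.tsv",
        ["group", "n", "mean", "sd", "median", "ci_lo", "ci_hi", "pct_ILS", "p_vs_reference"],
        [
            [
                s.group,
                s.n,
                _fmt(s.mean),
                _fmt(s.sd),
                _fmt(s.median),
                _fmt(s.ci95[0]) if s.ci95[0] == s.ci95[0] else "-",
                _fmt(s.ci95[1]) if s.ci95[1] == s.ci95[1] else "-",
                _fmt(s.pct_ils),
                format_p(s.p_vs_reference) if s.p_vs_reference is not None else "-",
            ]
            for s in summaries
        ],
    )

    km_rows = []
    groups = sorted({r.group for r in records})
    for group in groups:
        recs = [r for r in records if r.group == group]
        curve = km_estimate(
            [r.survival_days for r in recs], [r.event for r in recs]
        )
        for t, at_risk, s in zip(curve.event_times, curve.at_risk, curve.survival):
            km_rows.append([group, f"{t:g}", int(at_risk), f"{s:.6f}"])
    _write_tsv(
        config.outdir / "km_curves.csv",
        ["group", "time_days", "at_risk", "survival"],
        km_rows,
    )

    matrix = prepare_bbb_matrix(
        records, start_day=config.irradiation_start_day, missing="carry_forward"
    )
    bbb_rows = []
    for group in groups:
        mask = matrix.groups == group
        sub = matrix.scores[mask]
        for j, day in enumerate(matrix.days):
            mean = float(sub[:, j].mean())
            sd = float(sub[:, j].std(ddof=1)) if sub.shape[0] > 1 else 0.0
            bbb_rows.append([group, int(day), _fmt(mean), _fmt(sd), int(sub.shape[0])])
    _write_tsv(
        config.outdir / "bbb_group_means.csv",
        ["group", "day", "mean", "sd", "n"],
        bbb_rows,
    )

    manova = bbb_group_compare(matrix)
    _write_tsv(
        config.outdir / "bbb_manova.tsv",
        ["wilks_lambda", "F", "df_num", "df_den", "p", "days_used", "thinned"],
        [[
            f"{manova.wilks_lambda:.6f}",
            f"{manova.f_value:.4f}",
            f"{manova.df_num:g}",
            f"{manova.df_den:g}",
            format_p(manova.p),
            ";".join(str(d) for d in manova.days_used),
            manova.thinned,
        ]],
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages; raises on the first stage failure after logging it."""
    from datetime import datetime, timezone

    for path in (config.uptake_csv, config.biodistribution_csv, config.animals_csv):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    # orchestration guard: the reference group must exist before any stage runs
    animal_groups = {
        r.group
        for r in _io.read_animals(config.animals_csv, skip_invalid=True).records
    }
    if config.reference_group not in animal_groups:
        raise ValueError(
            f"reference group {config.reference_group!r} not present in "
            f"{sorted(animal_groups)}"
        )
    config.outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stages: dict[str, str] = {}
    stage_fns = [
        ("uptake", lambda: _stage_uptake(config)),
        ("biodistribution", lambda: _stage_biodistribution(config)),
    ]
    selected_time: float | None = None
    for name, fn in stage_fns:
        try:
            result = fn()
            if name == "biodistribution":
                selected_time = result
            stages[name] = "ok"
        except Exception as exc:
            stages[name] = f"failed: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            raise
    for name, fn in (
        ("dose", lambda: _stage_dose(config, selected_time)),
        ("efficacy", lambda: _stage_efficacy(config)),
    ):
        try:
            fn()
            stages[name] = "ok"
        except Exception as exc:
            stages[name] = f"failed: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            raise
    manifest = RunManifest(
        version=PACKAGE_VERSION,
        config_hash=_config_hash(config),
        inputs={
            str(p): _sha256(Path(p))
            for p in (
                config.uptake_csv,
                config.biodistribution_csv,
                config.animals_csv,
            )
        },
        stages=stages,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(config.outdir / "manifest.json")
    return manifest
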