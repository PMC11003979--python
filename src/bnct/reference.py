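"""Published summary statistics of the rat spinal-cord-glioma BNCT study.

These are the printed group-level summaries (means ± SD, medians, ratios,
tabulated doses) that the synthetic-data generator is calibrated to and the
reconstruction checks compare against. Individual-animal data were never
published; everything downstream of these numbers is recomputed by the
package.

Conventions: tissues are keyed ``tumor``, ``spinal cord``, ``brain``,
``blood``; times are hours after the end of the intravenous BPA infusion;
concentrations are μg ¹⁰B per g tissue (or per mL blood); survival is days
after tumour implantation.
"""

from __future__ import annotations

from .biodistribution import TimecourseSummary

__all__ = [
    "BIODISTRIBUTION",
    "BIODIST_N",
    "PRINTED_RATIOS",
    "UPTAKE",
    "IMPLANT_SURVIVAL",
    "IRRADIATION_SURVIVAL",
    "TABULATED_DOSES",
    "reference_summaries",
]

# Organ boron time courses: model -> tissue -> time_h -> (mean, sd) μg ¹⁰B/g.
BIODISTRIBUTION: dict[str, dict[str, dict[float, tuple[float, float]]]] = {
    "F98": {
        "tumor": {2.5: (26.6, 5.8), 6.0: (16.3, 3.6), 24.0: (3.0, 0.4)},
        "spinal cord": {2.5: (5.3, 1.3), 6.0: (4.0, 1.1), 24.0: (0.8, 0.2)},
        "brain": {2.5: (5.5, 0.5), 6.0: (4.2, 0.6), 24.0: (1.1, 0.5)},
        "blood": {2.5: (6.7, 0.7), 6.0: (4.7, 0.6), 24.0: (1.1, 0.2)},
    },
    "9L": {
        "tumor": {2.5: (15.3, 4.5), 6.0: (12.6, 2.3), 24.0: (6.0, 0.8)},
        "spinal cord": {2.5: (4.2, 0.6), 6.0: (3.3, 0.7), 24.0: (2.0, 0.7)},
        "brain": {2.5: (5.0, 0.7), 6.0: (4.7, 1.0), 24.0: (1.8, 0.6)},
        "blood": {2.5: (5.9, 0.5), 6.0: (5.0, 0.9), 24.0: (1.9, 0.5)},
    },
}

# Animals sampled per biodistribution time point: model -> time_h -> n.
BIODIST_N: dict[str, dict[float, int]] = {
    "F98": {2.5: 8, 6.0: 4, 24.0: 4},
    "9L": {2.5: 6, 6.0: 5, 24.0: 4},
}

# Printed tissue ratios: model -> time_h -> (T/SC, T/Bl, Bl/SC).
PRINTED_RATIOS: dict[str, dict[float, tuple[float, float, float]]] = {
    "F98": {2.5: (5.0, 4.0, 1.3), 6.0: (4.1, 3.5, 1.2), 24.0: (3.6, 2.8, 1.3)},
    "9L": {2.5: (3.7, 2.6, 1.4), 6.0: (3.8, 2.5, 1.5), 24.0: (3.0, 3.2, 1.0)},
}

# In vitro cellular uptake after 2.5 h BPA exposure:
# cell line -> exposure (μg B/mL) -> (mean, sd) in μg ¹⁰B per 10⁹ cells, n = 3.
UPTAKE: dict[str, dict[float, tuple[float, float]]] = {
    "F98": {5.0: (19.0, 3.2), 10.0: (42.3, 2.6), 20.0: (61.0, 2.9)},
    "9L": {5.0: (21.0, 1.3), 10.0: (33.1, 1.6), 20.0: (45.0, 4.5)},
}

# Survival of the untreated implantation models:
# label -> (n, mean, sd, median, (ci_lo, ci_hi)) in days.
IMPLANT_SURVIVAL: dict[str, tuple[int, float, float, float, tuple[float, float]]] = {
    "F98-1e4": (8, 12.6, 1.6, 12.5, (10.0, 14.0)),
    "F98-1e5": (13, 7.4, 0.8, 7.0, (6.0, 9.0)),
    "9L-1e4": (7, 19.6, 1.6, 20.0, (17.0, 22.0)),
    "9L-1e5": (13, 10.2, 1.0, 10.0, (9.0, 12.0)),
}

# The F98 therapeutic irradiation experiment:
# group -> (n, mean, sd, median, (ci_lo, ci_hi), %ILS vs untreated).
IRRADIATION_SURVIVAL: dict[
    str, tuple[int, float, float, float, tuple[float, float], float | None]
] = {
    "untreated": (8, 14.8, 1.1, 15.0, (13.0, 16.0), None),
    "neutron-only": (6, 15.5, 0.5, 15.5, (15.0, 16.0), 3.3),
    "BNCT": (8, 32.5, 2.6, 32.5, (29.0, 35.0), 116.7),
}

# Tabulated doses of the irradiation experiment:
# group -> tissue -> (absorbed Gy, photon-equivalent Gy-Eq).
TABULATED_DOSES: dict[str, dict[str, tuple[float, float]]] = {
    "neutron-only": {"spinal cord": (1.2, 2.3), "tumor": (1.2, 2.3)},
    "BNCT": {"spinal cord": (2.2, 3.5), "tumor": (5.8, 19.5)},
    "sham-neutron-only": {"spinal cord": (1.4, 2.4)},
    "sham-BNCT": {"spinal cord": (2.3, 3.6)},
}


def reference_summaries(model: str) -> list[TimecourseSummary]:
    """Published organ time-course summaries as ``TimecourseSummary`` rows."""
    if model not in BIODISTRIBUTION:
        raise KeyError(f"unknown model {model!r}; expected one of {sorted(BIODISTRIBUTION)}")
    rows = []
    for tissue, course in BIODISTRIBUTION[model].items():
        for time_h, (mean, sd) in course.items():
            rows.append(
                TimecourseSummary(
                    tissue=tissue,
                    time_h=time_h,
                    n=BIODIST_N[model][time_h],
                    mean=mean,
                    sd=sd,
                )
            )
    rows.sort(key=lambda s: (s.tissue, s.time_h))
    return rows
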