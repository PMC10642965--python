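"""Three-condition MALDI-TOF peak-pattern screen.

Given an m/z x brain-section intensity table with sections labeled focal
(fully sleep-deprived), yoked (identical mechanical stimulation, partial
sleep loss), and unperturbed, classify each peak by which signal it tracks:

* ``mechanical``      -- focal ~ yoked, both elevated over unperturbed:
                         a stimulus artifact;
* ``sleep_pressure``  -- unperturbed < yoked < focal, all pairwise
                         distinguishable: tracks graded sleep loss;
* ``sleep_absence``   -- elevated only in focal, yoked ~ unperturbed:
                         tracks the complete absence of sleep;
* ``NS``              -- omnibus BH-adjusted q >= alpha;
* ``other``           -- any remaining pattern (including peaks lower in
                         focal flies).

Test cascade: per-peak omnibus (Kruskal-Wallis across the three conditions,
or rank-sum focal-vs-unperturbed in ``no_yoking`` mode), BH correction
across the peak family, then Bonferroni-corrected pairwise rank-sum tests
within each gated peak, with direction taken from group medians.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .stats import bh_adjust, min_attainable_p, rank_sum
from scipy import stats as sps

__all__ = [
    "PeakTable",
    "PeakResult",
    "ScreenResult",
    "test_peaks",
    "classify_peak",
    "screen",
    "category_percentages",
    "serotonin_mz_check",
    "annotate_adduct_matches",
    "PROTON_MASS",
    "SEROTONIN_AVERAGE_MASS",
]

CONDITIONS = ("focal", "yoked", "unperturbed")
YOKED_CATEGORIES = ("NS", "mechanical", "sleep_pressure", "sleep_absence", "other")
NO_YOKING_CATEGORIES = ("NS", "positive_hit", "other_lower")

PROTON_MASS = 1.00728  # Da
SEROTONIN_AVERAGE_MASS = 176.2  # Da


@dataclass
class PeakTable:
    """m/z peaks x brain-ROI sections, with per-section condition labels."""

    mz: np.ndarray
    section_ids: tuple[str, ...]
    section_conditions: tuple[str, ...]
    intensities: np.ndarray  # (n_peaks, n_sections), > 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.mz.size, len(self.section_ids)):
            raise DataError("intensity matrix shape must be (n_peaks, n_sections)")
        if len(self.section_ids) != len(self.section_conditions):
            raise DataError("one condition label per section required")
        bad = set(self.section_conditions) - set(CONDITIONS)
        if bad:
            raise DataError(f"unknown section conditions: {sorted(bad)}")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities <= 0):
            raise DataError("intensities must be finite and strictly positive")
        for cond in set(self.section_conditions):
            if self.section_conditions.count(cond) < 2:
                raise DataError(f"need >= 2 sections for condition {cond!r}")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def condition_columns(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.section_conditions) if c == condition]
        if not idx:
            raise DataError(f"no sections with condition {condition!r}")
        return self.intensities[:, idx]

    def n_sections(self, condition: str) -> int:
        return self.section_conditions.count(condition)

    # -- CSV round trip (table + condition sidecar) ------------------------

    def to_csv(self, path: str | Path, sidecar_path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["mz", *self.section_ids])
            for k in range(self.n_peaks):
                w.writerow([f"{self.mz[k]:.1f}",
                            *(repr(float(v)) for v in self.intensities[k])])
        with open(sidecar_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["section_id", "condition"])
            for sid, cond in zip(self.section_ids, self.section_conditions):
                w.writerow([sid, cond])

    @classmethod
    def from_csv(cls, path: str | Path, sidecar_path: str | Path) -> "PeakTable":
        with open(sidecar_path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        cond_of = {r["section_id"]: r["condition"] for r in rows}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            section_ids = tuple(header[1:])
            mz, data = [], []
            for row in reader:
                mz.append(float(row[0]))
                data.append([float(v) for v in row[1:]])
        try:
            conditions = tuple(cond_of[s] for s in section_ids)
        except KeyError as exc:
            raise DataError(f"section {exc} missing from sidecar") from exc
        return cls(mz=np.array(mz), section_ids=section_ids,
                   section_conditions=conditions,
                   intensities=np.array(data))


def test_peaks(table: PeakTable, mode: str = "yoked",
               alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak omnibus raw p-values and BH q-values across the peak family.

    ``yoked`` mode: Kruskal-Wallis over focal/yoked/unperturbed.
    ``no_yoking`` mode: two-sided rank-sum, focal vs unperturbed only.
    """
    if mode not in ("yoked", "no_yoking"):
        raise ConfigurationError(f"unknown screen mode {mode!r}")
    focal = table.condition_columns("focal")
    unpert = table.condition_columns("unperturbed")
    if mode == "yoked":
        yoked = table.condition_columns("yoked")
    p = np.empty(table.n_peaks)
    for k in range(table.n_peaks):
        if mode == "yoked":
            groups = (focal[k], yoked[k], unpert[k])
            if all(np.ptp(g) == 0 for g in groups) and len(
                    {g[0] for g in groups}) == 1:
                p[k] = 1.0  # all-constant peak: no evidence by construction
            else:
                p[k] = float(sps.kruskal(*groups).pvalue)
        else:
            if np.ptp(focal[k]) == 0 and np.ptp(unpert[k]) == 0 \
                    and focal[k][0] == unpert[k][0]:
                p[k] = 1.0
            else:
                p[k] = rank_sum(focal[k], unpert[k]).p_value
    return p, bh_adjust(p)


def classify_peak(pairwise: dict[str, tuple[str, bool]], omnibus_q: float,
                  alpha: float = 0.05) -> str:
    """Category from the omnibus gate plus pairwise decisions.

    ``pairwise`` maps "FY", "FU", "YU" to (direction, significant) where
    direction is "higher"/"lower"/"tied" for the first-named condition.
    """
    if omnibus_q >= alpha:
        return "NS"
    fy_dir, fy_sig = pairwise["FY"]
    fu_dir, fu_sig = pairwise["FU"]
    yu_dir, yu_sig = pairwise["YU"]
    f_up_over_u = fu_sig and fu_dir == "higher"
    y_up_over_u = yu_sig and yu_dir == "higher"
    f_up_over_y = fy_sig and fy_dir == "higher"
    if not fy_sig and f_up_over_u and y_up_over_u:
        return "mechanical"
    if f_up_over_y and f_up_over_u and y_up_over_u:
        return "sleep_pressure"
    if f_up_over_y and f_up_over_u and not yu_sig:
        return "sleep_absence"
    return "other"


@dataclass
class PeakResult:
    mz: float
    raw_p: float
    q: float
    pairwise: dict[str, tuple[str, bool]]
    category: str


@dataclass
class ScreenResult:
    mode: str
    alpha: float
    peaks: list[PeakResult]
    category_counts: dict[str, int]
    qc: dict[str, float] = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def categories(self) -> list[str]:
        return [p.category for p in self.peaks]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["mz", "raw_p", "q", "FY", "FU", "YU", "category"])
            for p in self.peaks:
                def fmt(key):
                    if key not in p.pairwise:
                        return ""
                    d, s = p.pairwise[key]
                    return f"{d}:{'sig' if s else 'ns'}"
                w.writerow([f"{p.mz:.1f}", repr(float(p.raw_p)), repr(float(p.q)),
                            fmt("FY"), fmt("FU"), fmt("YU"), p.category])


def _pairwise_decisions(table: PeakTable, k: int,
                        alpha: float) -> dict[str, tuple[str, bool]]:
    cols = {c: table.condition_columns(c)[k] for c in CONDITIONS}
    raw = {
        "FY": rank_sum(cols["focal"], cols["yoked"]),
        "FU": rank_sum(cols["focal"], cols["unperturbed"]),
        "YU": rank_sum(cols["yoked"], cols["unperturbed"]),
    }
    out = {}
    for key, r in raw.items():
        p_adj = min(1.0, r.p_value * len(raw))  # Bonferroni within the peak
        out[key] = (r.direction, bool(p_adj < alpha))
    return out


def screen(table: PeakTable, mode: str = "yoked",
           alpha: float = 0.05) -> ScreenResult:
    """Full classification of a peak table plus category counts and QC.

    In ``no_yoking`` mode categories collapse to positive_hit (focal
    significantly higher than unperturbed), NS, and other_lower.
    """
    raw_p, q = test_peaks(table, mode, alpha)
    results = []
    if mode == "yoked":
        counts = dict.fromkeys(YOKED_CATEGORIES, 0)
        for k in range(table.n_peaks):
            if q[k] >= alpha:
                cat, pw = "NS", {}
            else:
                pw = _pairwise_decisions(table, k, alpha)
                cat = classify_peak(pw, q[k], alpha)
            counts[cat] += 1
            results.append(PeakResult(float(table.mz[k]), float(raw_p[k]),
                                      float(q[k]), pw, cat))
    else:
        counts = dict.fromkeys(NO_YOKING_CATEGORIES, 0)
        focal = table.condition_columns("focal")
        unpert = table.condition_columns("unperturbed")
        for k in range(table.n_peaks):
            if q[k] >= alpha:
                cat = "NS"
            elif np.median(focal[k]) > np.median(unpert[k]):
                cat = "positive_hit"
            else:
                cat = "other_lower"
            counts[cat] += 1
            results.append(PeakResult(float(table.mz[k]), float(raw_p[k]),
                                      float(q[k]), {}, cat))

    qc = {"min_attainable_p_FU": min_attainable_p(table.n_sections("focal"),
                                                  table.n_sections("unperturbed"))}
    if "yoked" in set(table.section_conditions):
        qc["min_attainable_p_FY"] = min_attainable_p(table.n_sections("focal"),
                                                     table.n_sections("yoked"))
        qc["min_attainable_p_YU"] = min_attainable_p(table.n_sections("yoked"),
                                                     table.n_sections("unperturbed"))
    return ScreenResult(mode=mode, alpha=alpha, peaks=results,
                        category_counts=counts, qc=qc)


def category_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Counts -> percentages of the total peak number, rounded."""
    total = sum(counts.values())
    if total == 0:
        raise DataError("no peaks counted")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def serotonin_mz_check(neutral_mass: float = SEROTONIN_AVERAGE_MASS,
                       adduct: str = "M+H") -> float:
    """Expected m/z of a singly protonated neutral (positive-ion DHB matrix).

    Serotonin (average mass 176.2 Da) gives ~177.2 as [M+H]+.
    """
    if adduct != "M+H":
        raise ConfigurationError(f"unknown adduct {adduct!r}")
    if neutral_mass < 0:
        raise ConfigurationError("mass must be non-negative")
    return neutral_mass + PROTON_MASS


def annotate_adduct_matches(mz_values, neutral_mass: float,
                            adduct: str = "M+H",
                            tolerance: float = 0.2) -> list[int]:
    """Indices of peaks within +/- tolerance Da of the computed adduct m/z."""
    target = serotonin_mz_check(neutral_mass, adduct)
    mz_values = np.asarray(mz_values, dtype=float)
    return [int(i) for i in np.flatnonzero(np.abs(mz_values - target) <= tolerance)]
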