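"""Group-level analysis of 2AFC duration-adaptation trial tables.

Per-participant cumulative-Gaussian fits give PSEs and JNDs for every
condition x standard cell; the pipeline then computes condition summaries
(mean, s.e.m.), per-participant adaptation effects (PSE change from baseline,
in % of the standard, negative = compression), paired t-tests between the
sub- and supra-second effects, the PSE-JND correlation, an exclusion
re-analysis dropping the participants with the highest baseline-600 PSEs,
and the count of participants showing stronger compression at the sub-second
standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from chronopop.psychometrics import PsychometricFit, fit_cumulative_gaussian

logger = logging.getLogger(__name__)

VALID_CONDITIONS = ("baseline", "adaptation")

#: canonical trial-table columns
TRIAL_COLUMNS = ("participant", "condition", "standard_ms", "comparison_pct", "response", "rep")


@dataclass(frozen=True)
class ConditionSummary:
    """Group summary of one condition x standard cell."""

    condition: str
    standard_ms: float
    participants: tuple[str, ...]
    pses: np.ndarray
    jnds: np.ndarray

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def mean_pse(self) -> float:
        return float(np.mean(self.pses))

    @property
    def sem_pse(self) -> float:
        return float(np.std(self.pses, ddof=1) / np.sqrt(self.n))

    @property
    def mean_jnd(self) -> float:
        return float(np.mean(self.jnds))

    @property
    def sem_jnd(self) -> float:
        return float(np.std(self.jnds, ddof=1) / np.sqrt(self.n))


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the pipeline computes from one trial table."""

    summaries: dict
    effects: pd.DataFrame
    fits: dict
    diagnostics: tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (condition, standard), s in sorted(self.summaries.items()):
            rows.append(
                {
                    "condition": condition,
                    "standard_ms": standard,
                    "n": s.n,
                    "mean_pse_pct": s.mean_pse,
                    "sem_pse_pct": s.sem_pse,
                    "mean_jnd_pct": s.mean_jnd,
                    "sem_jnd_pct": s.sem_jnd,
                }
            )
        return pd.DataFrame(rows)


def load_trials(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    The canonical dialect has header
    ``participant,condition,standard_ms,comparison_pct,response,rep``;
    ``column_map`` renames alternative layouts (``{file_column: canonical}``).
    Comparison values given in milliseconds (all positive, some exceeding
    100) are converted to signed % of the standard.  Invalid rows are
    reported with their line numbers.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no trial rows found")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "rep"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "rep" not in df.columns:
        df["rep"] = df.groupby(
            ["participant", "condition", "standard_ms", "comparison_pct"]
        ).cumcount()

    problems = []
    bad_cond = ~df["condition"].isin(VALID_CONDITIONS)
    for idx in df.index[bad_cond]:
        problems.append(
            f"line {idx + 2}: unknown condition {df.at[idx, 'condition']!r}"
        )
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad_resp = ~resp.isin([0, 1])
    for idx in df.index[bad_resp]:
        problems.append(f"line {idx + 2}: non-binary response {df.at[idx, 'response']!r}")
    if problems:
        shown = "\n".join(problems[:20])
        raise ValueError(f"{path}: {len(problems)} invalid rows\n{shown}")
    df["response"] = resp.astype(int)
    df["standard_ms"] = pd.to_numeric(df["standard_ms"])
    df["comparison_pct"] = pd.to_numeric(df["comparison_pct"])

    comp = df["comparison_pct"]
    if (comp > 100).any() or ((comp >= 0).all() and comp.max() > 100 * 2 / 3):
        # values are durations in ms, not signed percentages
        df["comparison_pct"] = 100.0 * (comp / df["standard_ms"] - 1.0)
        logger.info("converted comparison values from ms to %% of standard")
    df["participant"] = df["participant"].astype(str)
    return df[list(TRIAL_COLUMNS)]


def _fit_all_cells(trials: pd.DataFrame, lapse: float = 0.0, method: str = "mle"):
    fits: dict = {}
    diagnostics: list[str] = []
    for (participant, condition, standard), cell in trials.groupby(
        ["participant", "condition", "standard_ms"]
    ):
        fit = fit_cumulative_gaussian(cell, lapse=lapse, method=method)
        if not fit.converged:
            diagnostics.append(
                f"{participant}/{condition}/{standard:g}ms: {'; '.join(fit.flags) or 'not converged'}"
            )
            logger.debug("fit flags for %s/%s/%s: %s", participant, condition, standard, fit.flags)
        fits[(participant, condition, float(standard))] = fit
    return fits, diagnostics


def summarize_conditions(
    trials: pd.DataFrame, lapse: float = 0.0, method: str = "mle"
) -> AnalysisResult:
    """Per-participant fits -> condition summaries and adaptation-effect table.

    The effect table has one row per participant with the adaptation effect
    (PSE_adaptation - PSE_baseline, %) at each standard; participants missing
    a cell get NaN there.  Unconverged fits are surfaced in ``diagnostics``
    and retained (exclusion is the caller's decision).
    """
    fits, diagnostics = _fit_all_cells(trials, lapse=lapse, method=method)
    cells: dict = {}
    for (participant, condition, standard), fit in fits.items():
        cells.setdefault((condition, standard), []).append((participant, fit))
    summaries = {}
    for (condition, standard), pairs in cells.items():
        if len(pairs) < 2:
            raise ValueError(
                f"cell {condition}/{standard:g} ms has fewer than 2 participants"
            )
        pairs.sort(key=lambda t: t[0])
        summaries[(condition, standard)] = ConditionSummary(
            condition=condition,
            standard_ms=standard,
            participants=tuple(p for p, _ in pairs),
            pses=np.array([f.pse_pct for _, f in pairs]),
            jnds=np.array([f.jnd_pct for _, f in pairs]),
        )

    participants = sorted(trials["participant"].unique())
    standards = sorted(trials["standard_ms"].unique())
    rows = []
    for participant in participants:
        row = {"participant": participant}
        for standard in standards:
            fa = fits.get((participant, "adaptation", float(standard)))
            fb = fits.get((participant, "baseline", float(standard)))
            row[f"effect_{standard:g}"] = (
                fa.pse_pct - fb.pse_pct if fa is not None and fb is not None else np.nan
            )
        rows.append(row)
    effects = pd.DataFrame(rows).set_index("participant")
    return AnalysisResult(
        summaries=summaries, effects=effects, fits=fits, diagnostics=tuple(diagnostics)
    )


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired-samples t-test; returns ``(t, df, two-sided p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("pairwise-complete data required (NaNs present)")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            # identical pairs: the difference is exactly zero, define t = 0
            return 0.0, len(d) - 1, 1.0
        raise ValueError("zero variance of differences: t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)


def one_sample_t_test(x, popmean: float = 0.0) -> tuple[float, int, float]:
    """One-sample t-test against ``popmean``; returns ``(t, df, two-sided p)``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance: t undefined")
    res = sps.ttest_1samp(x, popmean)
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def exclusion_reanalysis(
    trials: pd.DataFrame, k: int = 3, lapse: float = 0.0, method: str = "mle"
) -> tuple[AnalysisResult, pd.DataFrame]:
    """Re-run the analysis without the ``k`` highest baseline-600 PSEs.

    Participants are ranked by their baseline PSE at the 600 ms standard and
    the top ``k`` removed; ties straddling the cut are refused (pass an
    explicit id list by filtering the table yourself in that case).  Returns
    the re-analysis and a table of the excluded participants with their PSEs.
    """
    full = summarize_conditions(trials, lapse=lapse, method=method)
    base600 = full.summaries.get(("baseline", 600.0))
    if base600 is None:
        raise ValueError("no baseline 600 ms cell in the table")
    if k == 0:
        return full, pd.DataFrame(columns=["participant", "baseline_600_pse_pct"])
    if base600.n < k + 2:
        raise ValueError(f"need at least {k + 2} participants to exclude {k}")
    order = np.argsort(base600.pses)[::-1]
    cut_pse = base600.pses[order[k - 1]]
    next_pse = base600.pses[order[k]]
    if cut_pse == next_pse:
        raise ValueError(
            f"tie at the exclusion boundary (PSE {cut_pse}); "
            "exclude an explicit participant list instead"
        )
    excluded = [base600.participants[i] for i in order[:k]]
    excluded_tbl = pd.DataFrame(
        {
            "participant": excluded,
            "baseline_600_pse_pct": [base600.pses[i] for i in order[:k]],
        }
    )
    kept = trials[~trials["participant"].isin(excluded)]
    return summarize_conditions(kept, lapse=lapse, method=method), excluded_tbl


def count_stronger_effect(effects: pd.DataFrame) -> tuple[int, int]:
    """Participants with stronger sub-second compression.

    Counts rows with ``effect_600 < effect_1200`` (more negative = stronger
    compression); rows missing either effect are skipped with a warning.
    Returns ``(count, n_complete)``.
    """
    cols = [c for c in ("effect_600", "effect_1200") if c in effects.columns]
    if len(cols) != 2:
        raise ValueError("effect table must contain effect_600 and effect_1200")
    complete = effects.dropna(subset=cols)
    skipped = len(effects) - len(complete)
    if skipped:
        logger.warning("%d participants missing one standard; skipped", skipped)
    count = int((complete["effect_600"] < complete["effect_1200"]).sum())
    return count, len(complete)


def analyze_trials(
    trials: pd.DataFrame, lapse: float = 0.0, method: str = "mle", exclusion_k: int = 3
) -> dict:
    """Run the full group analysis battery; returns a nested result dict.

    Contents: condition summaries and effects (``result``), the paired t of
    the 600 vs 1200 ms effects, the one-sample t of the baseline-600 PSEs,
    the baseline-600 PSE-JND Pearson correlation, the stronger-compression
    count, and (when enough participants) the exclusion re-analysis.
    """
    result = summarize_conditions(trials, lapse=lapse, method=method)
    out: dict = {"result": result}
    eff = result.effects
    if {"effect_600", "effect_1200"}.issubset(eff.columns):
        complete = eff.dropna()
        if len(complete) >= 2:
            t, df, p = paired_t_test(complete["effect_600"], complete["effect_1200"])
            out["paired_t_effects"] = {"t": t, "df": df, "p": p}
        count, n = count_stronger_effect(eff)
        out["stronger_at_600"] = {"count": count, "n": n}
    base600 = result.summaries.get(("baseline", 600.0))
    if base600 is not None and base600.n >= 3:
        t, df, p = one_sample_t_test(base600.pses)
        out["baseline_600_vs_zero"] = {"t": t, "df": df, "p": p}
        out["baseline_600_pse_jnd_r"] = pearson_correlation(base600.pses, base600.jnds)
    if base600 is not None and base600.n >= exclusion_k + 2 and exclusion_k > 0:
        reanalysis, excluded = exclusion_reanalysis(
            trials, k=exclusion_k, lapse=lapse, method=method
        )
        out["exclusion"] = {"result": reanalysis, "excluded": excluded}
    return out
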