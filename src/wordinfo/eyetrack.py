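"""Interest-area eye-movement pipeline: ingest, filter, derive, model table.

Fixation reports are word-token ("interest area") level tables with one row
per (subject, trial, word position), carrying first fixation duration (FFD),
gaze duration (first-pass sum) and total fixation duration (TFD) in
milliseconds; a word never fixated has all three missing, a word skipped on
the first pass but fixated later has FFD/gaze missing with TFD present.

The pipeline applies the standard outlier filters (fixated words with
TFD < 80 ms or > 2000 ms, FFD > 800 ms, or gaze > 1000 ms are removed;
comparisons strict), derives the five dependent variables (first-run skip,
log FFD, log gaze, log TFD, rereading), z-standardizes individual-difference
tests into a composite skill score, joins everything with the word-level
covariates into a centered/scaled model table, and offers a desk-scale
fixed-effects check in which subject and word-within-language intercepts are
absorbed as categorical dummies. The check validates table construction and
planted-effect recovery; it is not a substitute for full crossed
random-effects estimation, which the exported table is designed to feed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ParseError,
    RankDeficiencyError,
    SchemaError,
    SeparationError,
    UndefinedStatisticError,
)

IA_REQUIRED_COLUMNS = ("subject", "language", "trial", "ia_index", "word",
                       "ffd", "gaze", "tfd")
DURATION_COLUMNS = ("ffd", "gaze", "tfd")

#: Filter bounds in ms; all comparisons strict, matching "shorter than" /
#: "longer than" phrasing.
TFD_MIN_MS = 80.0
TFD_MAX_MS = 2000.0
FFD_MAX_MS = 800.0
GAZE_MAX_MS = 1000.0

SKILL_TESTS = ("towre_word", "towre_nonword", "spelling", "lextale", "vocabulary")

BINARY_DVS = ("skip", "reread")
CONTINUOUS_DVS = ("log_ffd", "log_gaze", "log_tfd")

SCALED_COVARIATES = ("length", "zipf", "predictability", "informativeness",
                     "surprisal", "composite")


def read_ia_report(path: str | Path) -> pd.DataFrame:
    """Read an interest-area fixation report (CSV or TSV by extension).

    Required columns: subject, language, trial, ia_index, word, ffd, gaze,
    tfd. Durations are milliseconds; empty cells and "NA" are missing.

    Raises
    ------
    SchemaError
        Naming the first missing required column.
    ParseError
        Naming the first row with a non-numeric duration.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject": str, "language": str,
                                           "trial": str, "word": str},
                     na_values=["NA", "na", ""], keep_default_na=True)
    for col in IA_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in DURATION_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ParseError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = coerced
    df["ia_index"] = pd.to_numeric(df["ia_index"], errors="raise").astype(int)
    return df


def validate_ia(df: pd.DataFrame) -> None:
    """Assert the structural invariants of an interest-area table."""
    fix = df[df["tfd"].notna()]
    both = fix[fix["gaze"].notna() & fix["ffd"].notna()]
    if not ((both["ffd"] <= both["gaze"]).all() and (fix["gaze"].dropna() <= fix.loc[fix["gaze"].notna(), "tfd"]).all()):
        raise ValueError("duration ordering violated: need ffd <= gaze <= tfd")
    skipped = df["ffd"].isna() & df["gaze"].isna() & df["tfd"].isna()
    partial = df["tfd"].isna() & (df["ffd"].notna() | df["gaze"].notna())
    if partial.any():
        raise ValueError("rows with ffd/gaze but no tfd are inconsistent")
    _ = skipped  # skipped rows are legitimate; nothing further to assert


def filter_ia(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the duration outlier filters to fixated interest areas.

    Fixated rows (TFD present) are removed when TFD < 80 ms, TFD > 2000 ms,
    FFD > 800 ms, or gaze > 1000 ms — all strict. Words without any fixation
    carry no durations and are retained. Returns the kept rows plus a log of
    per-rule counts and the overall proportion removed. Idempotent.
    """
    tfd, ffd, gaze = df["tfd"], df["ffd"], df["gaze"]
    fixated = tfd.notna()
    too_short = fixated & (tfd < TFD_MIN_MS)
    too_long = fixated & (tfd > TFD_MAX_MS)
    ffd_long = ffd.notna() & (ffd > FFD_MAX_MS)
    gaze_long = gaze.notna() & (gaze > GAZE_MAX_MS)
    removed = too_short | too_long | ffd_long | gaze_long
    log = {
        "n_input": int(len(df)),
        "tfd_below_min": int(too_short.sum()),
        "tfd_above_max": int(too_long.sum()),
        "ffd_above_max": int(ffd_long.sum()),
        "gaze_above_max": int(gaze_long.sum()),
        "n_removed": int(removed.sum()),
        "proportion_removed": float(removed.mean()) if len(df) else 0.0,
    }
    return df.loc[~removed].copy(), log


def derive_dvs(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the five dependent variables to a (filtered) interest-area table.

    ``skip`` — defined for every word: 1 when the word got no first-pass
    fixation (gaze missing). ``log_ffd``/``log_gaze``/``log_tfd`` — natural
    log of the millisecond durations, defined only where the duration exists.
    ``reread`` — defined for words fixated at least once: 1 when gaze
    returned after the first pass (TFD > gaze, or first-pass skip with a
    later fixation).
    """
    out = df.copy()
    fixated = out["tfd"].notna()
    out["skip"] = (out["gaze"].isna()).astype(float)
    for col in DURATION_COLUMNS:
        out[f"log_{col}"] = np.log(out[col])
    reread = np.where(
        fixated,
        np.where(out["gaze"].notna(), (out["tfd"] > out["gaze"]).astype(float), 1.0),
        np.nan,
    )
    out["reread"] = reread
    return out


def composite_skill(scores: pd.DataFrame,
                    tests: tuple[str, ...] = SKILL_TESTS) -> tuple[pd.DataFrame, dict]:
    """Z-standardize each proficiency test over subjects and average into a composite.

    The composite is the mean of the available z-scores per subject; tests a
    subject is missing are dropped from that subject's mean, with the count
    kept in ``n_tests_used``. A test constant across subjects has no defined
    z-score; it is reported in the log and excluded for everyone.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 2 subjects (no variance to standardize against).
    """
    if scores["subject"].nunique() < 2:
        raise UndefinedStatisticError("z-standardization needs at least 2 subjects")
    out = scores.copy()
    undefined: list[str] = []
    zcols = []
    for t in tests:
        if t not in out.columns:
            continue
        x = out[t].astype(float)
        sd = x.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            undefined.append(t)
            out[f"z_{t}"] = np.nan
        else:
            out[f"z_{t}"] = (x - x.mean()) / sd
        zcols.append(f"z_{t}")
    z = out[zcols]
    out["composite"] = z.mean(axis=1, skipna=True)
    out["n_tests_used"] = z.notna().sum(axis=1)
    return out, {"undefined_tests": undefined, "tests_used": zcols}


@dataclass
class ModelTable:
    """Model-ready analysis table with its scaling metadata.

    ``data`` holds one row per retained (subject, word token) with DVs,
    centered/scaled covariates and grouping keys; ``scaling`` records the
    raw mean and sd used per covariate so estimates can be unscaled.
    """

    data: pd.DataFrame
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_dropped_outliers: int = 0

    def __len__(self) -> int:
        return len(self.data)


def _check_cov(df: pd.DataFrame, value_col: str, keys: list[str]) -> pd.DataFrame:
    missing = [k for k in keys + [value_col] if k not in df.columns]
    if missing:
        raise SchemaError(f"covariate table for {value_col!r} lacks columns {missing}")
    if df.duplicated(subset=keys).any():
        raise ValueError(f"duplicate join keys in {value_col!r} covariate table")
    return df[keys + [value_col]]


def build_model_table(
    ia: pd.DataFrame,
    informativeness: pd.DataFrame,
    zipf: pd.DataFrame | None = None,
    predictability: pd.DataFrame | None = None,
    surprisal: pd.DataFrame | None = None,
    skills: pd.DataFrame | None = None,
    scale_within_language: bool = False,
    outlier_threshold: float = -10.0,
) -> ModelTable:
    """Join eye-movement DVs with word covariates into a centered/scaled table.

    ``ia`` is a filtered, DV-derived interest-area table. Word-level
    covariate tables are keyed by (language, trial, ia_index) and carry one
    value column named after themselves (``informativeness`` must also carry
    ``outlier``); ``skills`` is keyed by subject and contributes
    ``composite``. All joins are inner; words with outlier-flagged
    informativeness are dropped before scaling. ``length`` is derived from
    the word form (printed characters). Covariates are centered and scaled
    pooled across languages by default (``scale_within_language`` switches to
    per-language standardization).
    """
    keys = ["language", "trial", "ia_index"]
    df = ia.copy()
    df["word"] = df["word"].astype(str)
    df["length"] = df["word"].str.len().astype(float)

    info = _check_cov(informativeness, "informativeness", keys).copy()
    if "outlier" in informativeness.columns:
        info["outlier"] = informativeness["outlier"].astype(bool).to_numpy()
    else:
        info["outlier"] = info["informativeness"] < outlier_threshold
    n_out = int(info["outlier"].sum())
    info = info.loc[~info["outlier"]].drop(columns="outlier")
    df = df.merge(info, on=keys, how="inner", validate="many_to_one")

    for name, cov in (("zipf", zipf), ("predictability", predictability),
                      ("surprisal", surprisal)):
        if cov is not None:
            df = df.merge(_check_cov(cov, name, keys), on=keys, how="inner",
                          validate="many_to_one")
    if skills is not None:
        if "composite" not in skills.columns:
            raise SchemaError("skills table must carry a 'composite' column")
        df = df.merge(skills[["subject", "composite"]], on="subject", how="inner",
                      validate="many_to_one")
    if df.empty:
        raise ValueError("model table is empty after joins")

    df["word_in_language"] = df["language"].astype(str) + ":" + df["word"]

    scaling: dict[str, tuple[float, float]] = {}
    for col in SCALED_COVARIATES:
        if col not in df.columns:
            continue
        if scale_within_language:
            grp = df.groupby("language")[col]
            mu, sd = grp.transform("mean"), grp.transform(lambda s: s.std(ddof=0))
            scaling[col] = (float("nan"), float("nan"))  # per-language; see data
        else:
            mu, sd = df[col].mean(), df[col].std(ddof=0)
            scaling[col] = (float(mu), float(sd))
        df[col] = (df[col] - mu) / sd
    return ModelTable(data=df, scaling=scaling, n_dropped_outliers=n_out)


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect estimate from the desk-scale check."""

    dv: str
    term: str
    beta: float
    se: float
    n_obs: int


def _design(table: pd.DataFrame, terms: list[str]
            ) -> tuple[np.ndarray, list[str], np.ndarray]:
    cols = [np.ones(len(table))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols.append((table[a] * table[b]).to_numpy(dtype=float))
        else:
            cols.append(table[t].to_numpy(dtype=float))
    X_terms = np.column_stack(cols)
    if np.linalg.matrix_rank(X_terms) < X_terms.shape[1]:
        raise RankDeficiencyError(f"collinear terms among {terms}")
    dummies = []
    for g in ("subject", "word_in_language"):
        d = pd.get_dummies(table[g], drop_first=True, dtype=float)
        dummies.append(d.to_numpy())
    X = np.hstack([X_terms] + dummies)
    names = ["(intercept)"] + terms
    penalized = np.zeros(X.shape[1])
    penalized[X_terms.shape[1]:] = 1.0
    return X, names, penalized


#: Ridge penalty applied to the absorbed group dummies. Unpenalized group
#: dummies would make group-constant covariates (word length and frequency
#: are constant within a word type; the skill composite is constant within a
#: subject) exactly collinear with the intercepts; shrinking the dummies is
#: the least-squares analogue of treating the intercepts as random, which is
#: how such covariates are estimable in the mixed models this check stands
#: in for.
GROUP_RIDGE = 10.0


def fit_effect_check(table: ModelTable, dv: str, terms: list[str],
                     min_rows: int = 50,
                     group_ridge: float = GROUP_RIDGE) -> list[EffectEstimate]:
    """Desk-scale fixed-effects validation fit.

    Absorbs subject and word-within-language intercepts as ridge-shrunk
    categorical dummies and estimates the requested terms by least squares
    (continuous DVs) or Newton-iterated logistic regression (binary DVs).
    Interaction terms are written ``"a:b"``. This is a validation-grade
    approximation for checking table construction and planted effects, not a
    crossed random-effects fit.

    Raises
    ------
    ValueError for degenerate tables, RankDeficiencyError for collinear
    terms, SeparationError for (near-)separated logistic fits.
    """
    df = table.data
    base_cols = {c for t in terms for c in (t.split(":") if ":" in t else [t])}
    sub = df.dropna(subset=[dv, *base_cols])
    if len(sub) < min_rows:
        raise ValueError(f"only {len(sub)} usable rows for dv {dv!r}; need >= {min_rows}")
    y = sub[dv].to_numpy(dtype=float)
    X, names, penalized = _design(sub, terms)
    pen = group_ridge * penalized
    if dv in BINARY_DVS or set(np.unique(y)) <= {0.0, 1.0}:
        beta, cov = _fit_logistic(X, y, pen)
    else:
        beta, cov = _fit_ols(X, y, pen)
    se = np.sqrt(np.diag(cov))
    return [
        EffectEstimate(dv=dv, term=t, beta=float(beta[i]), se=float(se[i]),
                       n_obs=len(sub))
        for i, t in enumerate(names) if t != "(intercept)"
    ]


def _fit_ols(X: np.ndarray, y: np.ndarray,
             pen: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    XtX = X.T @ X
    A = XtX + np.diag(pen)
    try:
        np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError("design matrix is rank deficient") from exc
    A_inv = np.linalg.solve(A, np.eye(p))
    beta = A_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / max(n - p, 1)
    cov = sigma2 * (A_inv @ XtX @ A_inv)  # sandwich for the ridge-shrunk fit
    return beta, cov


def _fit_logistic(X: np.ndarray, y: np.ndarray, pen: np.ndarray,
                  max_iter: int = 50, tol: float = 1e-8
                  ) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    beta = np.zeros(p)
    D = np.diag(pen)
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 30:
            raise SeparationError("fitted logits diverging; data may be separated")
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        XtWX = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(XtWX + D + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError("weighted design is rank deficient") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    XtWX = (X * w[:, None]).T @ X
    A_inv = np.linalg.solve(XtWX + D + 1e-10 * np.eye(p), np.eye(p))
    cov = A_inv @ XtWX @ A_inv
    return beta, cov
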