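"""Nonparametric multiplicative regression (NPMR) for a binary response.

The estimate of P(presence) at a target point is a leave-one-out weighted
average of the binary response over all other sample units, with the weight
of unit *i* at target *t* the product of univariate Gaussian kernels,

    w_ti = prod_j exp(-0.5 ((x_tj - x_ij) / sigma_j)^2),

one factor per continuous predictor (standard deviation sigma_j is the
predictor's "tolerance"), times an exact-match indicator for each
categorical predictor.  The sum of weights at a target is its environmental
neighborhood size n*; estimates are withheld where n* falls below a minimum
(0.25 x the average neighborhood size by default).

Model quality is the log (base-10) likelihood ratio logB against a naive
model that predicts the observed prevalence everywhere; B_ave = 10^(logB/SU)
is its per-sample-unit equivalent, xR2 the cross-validated pseudo-R2, and
chi2 = 2 ln(10) logB the corresponding deviance.  Model selection is a
forward free search over candidate predictors with a grid of tolerances
(fractions of each predictor's range), guarded by overfitting controls: a
data:predictor ratio cap, and a minimum logB improvement to accept a larger
model.  Tuning refines tolerances locally; bootstrap and response-shuffling
randomization quantify stability and significance of logB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LN10 = float(np.log(10.0))


@dataclass
class NPMRConfig:
    """Search and overfitting controls ("medium" defaults)."""

    tolerance_grid: tuple = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    n_min_fraction: float = 0.25
    nudge_fraction: float = 0.05
    min_logB_improvement_fraction: float = 0.05
    min_logB_improvement_absolute: float = 1.0   # when incumbent logB <= 0
    data_predictor_ratio: int = 30
    seed: int = 0
    n_boot: int = 100
    n_randomizations: int = 100

    def __post_init__(self) -> None:
        for name in ("n_min_fraction", "nudge_fraction",
                     "min_logB_improvement_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if min(self.n_boot, self.n_randomizations) < 1:
            raise ValueError("n_boot and n_randomizations must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Predictors of one model: continuous name -> tolerance, plus categoricals."""

    tolerances: tuple              # ((name, sigma), ...) in predictor units
    categorical: tuple = ()

    @classmethod
    def of(cls, tolerances: dict, categorical=()) -> "ModelSpec":
        for name, s in tolerances.items():
            if s <= 0:
                raise ValueError(f"tolerance for {name!r} must be positive")
        return cls(tuple(tolerances.items()), tuple(categorical))

    @property
    def continuous(self) -> dict:
        return dict(self.tolerances)

    @property
    def predictors(self) -> tuple:
        return tuple(n for n, _ in self.tolerances) + self.categorical

    def to_dict(self) -> dict:
        return {"tolerances": dict(self.tolerances),
                "categorical": list(self.categorical)}


@dataclass
class NPMRFit:
    """A fitted (or validated) model with per-row estimates and statistics."""

    spec: ModelSpec
    index: pd.Index            # complete-case rows, aligned with table
    estimates: np.ndarray      # LOO (or prediction) estimates; NaN below n_min
    nstar: np.ndarray          # neighborhood size per complete row
    su: int                    # sample units in populated neighborhoods
    n_ave: float
    n_min: float
    logB: float
    b_ave: float
    xr2: float
    r: float
    chi2: float
    prevalence: float
    n_complete: int
    ranges: dict               # predictor -> observed range used for scaling
    kind: str = "building"
    sensitivities: dict = field(default_factory=dict)

    def tolerance_pct(self) -> dict:
        return {name: tolerance_pct(s, self.ranges[name])
                for name, s in self.spec.tolerances}

    def summary(self) -> dict:
        return {
            "predictors": list(self.spec.predictors),
            "tolerances": dict(self.spec.tolerances),
            "tolerance_pct": self.tolerance_pct(),
            "SU": self.su, "N_ave": self.n_ave, "n_min": self.n_min,
            "logB": self.logB, "B_ave": self.b_ave, "xR2": self.xr2,
            "r": self.r, "chi2": self.chi2,
            "prevalence": self.prevalence, "n_complete": self.n_complete,
            "sensitivity": dict(self.sensitivities), "kind": self.kind,
        }

    def to_json(self, path) -> None:
        """Serialize spec, statistics and per-row estimates (keyed by row id)."""
        import json
        from pathlib import Path
        payload = self.summary()
        payload["estimates"] = {
            str(idx): (None if not np.isfinite(e) else float(e))
            for idx, e in zip(self.index, self.estimates)}
        payload["nstar"] = {str(idx): float(n)
                            for idx, n in zip(self.index, self.nstar)}
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


@dataclass
class SearchResult:
    best_per_size: list        # dicts: size, predictors, tolerances, logB, N_ave
    fit: NPMRFit               # the chosen final model
    accepted_sizes: list
    notes: list


def tolerance_pct(sigma: float, predictor_range: float) -> float:
    """Tolerance as a percentage of the predictor's range (1 dp)."""
    if predictor_range <= 0:
        raise ValueError("predictor range must be positive")
    return round(100.0 * sigma / predictor_range, 1)


def b_ave(logB: float, su: int) -> float:
    """Average per-sample-unit contribution to the likelihood ratio."""
    return float(10.0 ** (logB / su))


def log_likelihood_ratio(y, yhat, p_bar=None, clamp: bool = True) -> float:
    """logB = sum log10 L(y|yhat) / L(y|p_bar) for Bernoulli likelihoods.

    Estimates are clamped to [eps, 1-eps], eps = 1/(2 SU), before
    evaluation so a pure neighborhood cannot contribute an infinite term.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(yhat, dtype=float)
    su = y.size
    if su == 0:
        raise ValueError("no sample units")
    pb = float(np.mean(y)) if p_bar is None else float(p_bar)
    if clamp:
        eps = 1.0 / (2.0 * su)
        p = np.clip(p, eps, 1.0 - eps)
        pb = min(max(pb, eps), 1.0 - eps)
    like = np.where(y == 1.0, p, 1.0 - p)
    naive = np.where(y == 1.0, pb, 1.0 - pb)
    return float(np.sum(np.log10(like) - np.log10(naive)))


def kernel_weight(target_row, other_row, spec: ModelSpec) -> float:
    """Multiplicative kernel weight between two sample units."""
    w = 1.0
    for name, sigma in spec.tolerances:
        if sigma <= 0:
            raise ValueError(f"tolerance for {name!r} must be positive")
        dx = float(target_row[name]) - float(other_row[name])
        w *= float(np.exp(-0.5 * (dx / sigma) ** 2))
    for name in spec.categorical:
        w *= 1.0 if target_row[name] == other_row[name] else 0.0
    return w


class NPMREngine:
    """Caches pairwise squared differences per predictor for one table.

    All heavy operations (fit, search, tune, bootstrap, randomization) go
    through one engine so tolerance scans reuse the cached matrices.
    """

    def __init__(self, table: pd.DataFrame, y_col: str = "y",
                 config: NPMRConfig | None = None):
        self.table = table.reset_index(drop=True)
        self.orig_index = table.index
        self.y_col = y_col
        self.config = config or NPMRConfig()
        self.y = self.table[y_col].to_numpy(dtype=float)
        self._sqdiff: dict[str, np.ndarray] = {}
        self._catneq: dict[str, np.ndarray] = {}

    # -- cached pairwise pieces ------------------------------------------
    def _sq(self, name: str) -> np.ndarray:
        if name not in self._sqdiff:
            x = self.table[name].to_numpy(dtype=float)
            d = x[:, None] - x[None, :]
            self._sqdiff[name] = d * d
        return self._sqdiff[name]

    def _neq(self, name: str) -> np.ndarray:
        if name not in self._catneq:
            c = self.table[name].to_numpy()
            self._catneq[name] = c[:, None] != c[None, :]
        return self._catneq[name]

    def complete_rows(self, spec: ModelSpec) -> np.ndarray:
        ok = np.isfinite(self.y)
        for name, _ in spec.tolerances:
            ok &= np.isfinite(self.table[name].to_numpy(dtype=float))
        for name in spec.categorical:
            ok &= self.table[name].notna().to_numpy()
        return np.nonzero(ok)[0]

    def predictor_range(self, name: str) -> float:
        x = self.table[name].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"predictor {name!r} has no observed values")
        return float(x.max() - x.min())

    def weight_matrix(self, spec: ModelSpec, rows: np.ndarray) -> np.ndarray:
        s = np.zeros((rows.size, rows.size))
        ix = np.ix_(rows, rows)
        for name, sigma in spec.tolerances:
            if sigma <= 0:
                raise ValueError(f"tolerance for {name!r} must be positive")
            s += self._sq(name)[ix] / (sigma * sigma)
        w = np.exp(-0.5 * s)
        for name in spec.categorical:
            w[self._neq(name)[ix]] = 0.0
        return w

    # -- fitting ----------------------------------------------------------
    def fit(self, spec: ModelSpec, rows: np.ndarray | None = None,
            y: np.ndarray | None = None, enforce_ratio: bool = True) -> NPMRFit:
        """LOO-cross-validated fit of one model on the complete-case rows."""
        cfg = self.config
        rows = self.complete_rows(spec) if rows is None else np.asarray(rows)
        n = rows.size
        n_pred = len(spec.predictors)
        if enforce_ratio and n < 10 * max(n_pred, 1):
            raise ValueError(
                f"{n} complete rows < 10 x {n_pred} predictors")
        if n < 2:
            raise ValueError("need at least 2 complete rows")
        yv = self.y[rows] if y is None else np.asarray(y, dtype=float)[rows]

        w = self.weight_matrix(spec, rows)
        np.fill_diagonal(w, 0.0)
        nstar = w.sum(axis=1)
        n_min = cfg.n_min_fraction * float(nstar.mean())
        populated = nstar >= max(n_min, np.finfo(float).tiny)
        su = int(populated.sum())
        if su == 0:
            raise ValueError("no populated neighborhoods (SU = 0)")
        est = np.full(n, np.nan)
        est[populated] = (w[populated] @ yv) / nstar[populated]

        ranges = {name: self.predictor_range(name) for name, _ in spec.tolerances}
        return _finalize_fit(spec, self.orig_index[rows], est, nstar, su, n_min,
                             yv, n, ranges)

    # -- stepwise search --------------------------------------------------
    def scan_candidate(self, base: dict, base_cat: tuple, cand: str,
                       categorical: set, grid=None):
        """Best (logB, spec, fit) adding one candidate to the base model."""
        cfg = self.config
        best = None
        if cand in categorical:
            spec = ModelSpec.of(base, categorical=base_cat + (cand,))
            try:
                f = self.fit(spec)
                best = (f.logB, spec, f)
            except ValueError:
                pass
            return best
        rng = self.predictor_range(cand)
        if rng <= 0:
            return None
        for frac in sorted(grid or cfg.tolerance_grid, reverse=True):
            spec = ModelSpec.of({**base, cand: frac * rng}, categorical=base_cat)
            try:
                f = self.fit(spec)
            except ValueError:
                continue
            if best is None or f.logB > best[0] + 1e-12:
                best = (f.logB, spec, f)
        return best

    def free_search(self, candidates, categorical=()) -> SearchResult:
        """Forward-stepwise search with tolerance-grid scans per added predictor.

        A larger model is accepted only if its logB beats the incumbent by
        the configured fraction (or absolute floor when incumbent <= 0).
        Deterministic: candidate order and the larger-tolerance-first grid
        break ties.
        """
        cfg = self.config
        catset = set(categorical)
        n_rows = int(np.isfinite(self.y).sum())
        max_pred = max(1, min(len(candidates), n_rows // cfg.data_predictor_ratio))
        remaining = list(candidates)
        current: dict = {}
        current_cat: tuple = ()
        incumbent: NPMRFit | None = None
        best_per_size, accepted, notes = [], [], []

        for size in range(1, max_pred + 1):
            best = None
            for cand in remaining:
                got = self.scan_candidate(current, current_cat, cand, catset)
                if got is None:
                    continue
                if best is None or got[0] > best[0] + 1e-12:
                    best = got + (cand,)
            if best is None:
                notes.append(f"size {size}: no candidate produced a fit")
                break
            logB, spec, f, cand = best
            best_per_size.append({"size": size,
                                  "predictors": list(spec.predictors),
                                  "tolerances": dict(spec.tolerances),
                                  "logB": logB, "N_ave": f.n_ave})
            if incumbent is None:
                accept = True
            elif incumbent.logB > 0:
                accept = logB >= incumbent.logB * (
                    1.0 + cfg.min_logB_improvement_fraction)
            else:
                accept = logB >= incumbent.logB + cfg.min_logB_improvement_absolute
            if not accept:
                notes.append(f"size {size}: improvement below threshold, "
                             "keeping the smaller model")
                break
            incumbent = f
            accepted.append(size)
            remaining.remove(cand)
            if cand in catset:
                current_cat = current_cat + (cand,)
            else:
                current = dict(spec.tolerances)
        if incumbent is None:
            raise ValueError("no candidate yielded a populated-neighborhood fit")
        return SearchResult(best_per_size, incumbent, accepted, notes)

    def tune(self, fit: NPMRFit, min_gain: float = 0.01) -> NPMRFit:
        """Coordinate-wise local refinement of tolerances.

        Each tolerance is scanned over +/- one coarse grid step in five
        subdivisions; passes repeat until a full pass gains < ``min_gain``
        logB.  Never returns a fit with lower logB than the input.
        """
        best = fit
        step_frac = float(np.diff(sorted(self.config.tolerance_grid)).min()
                          if len(self.config.tolerance_grid) > 1 else 0.05)
        for _ in range(20):
            gained = 0.0
            for name, _ in best.spec.tolerances:
                rng = self.predictor_range(name)
                step = step_frac * rng
                sigma0 = dict(best.spec.tolerances)[name]
                for offset in np.linspace(-step, step, 11):
                    sigma = sigma0 + float(offset)
                    if sigma <= 0 or abs(offset) < 1e-12:
                        continue
                    tols = dict(best.spec.tolerances)
                    tols[name] = sigma
                    try:
                        f = self.fit(ModelSpec.of(tols, best.spec.categorical))
                    except ValueError:
                        continue
                    if f.logB > best.logB + 1e-12:
                        gained += f.logB - best.logB
                        best = f
            if gained < min_gain:
                break
        return best

    # -- resampling -------------------------------------------------------
    def bootstrap_logB(self, spec: ModelSpec, n_boot: int | None = None,
                       seed: int | None = None) -> dict:
        """Percentile interval of logB under case resampling.

        The model (predictors and tolerances) is held fixed; rows are
        resampled with replacement and the model refitted per replicate.
        Replicates with no populated neighborhood are recorded as missing.
        """
        cfg = self.config
        n_boot = cfg.n_boot if n_boot is None else n_boot
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        rows = self.complete_rows(spec)
        vals = []
        for _ in range(n_boot):
            idx = rng.choice(rows, size=rows.size, replace=True)
            try:
                vals.append(self.fit(spec, rows=idx, enforce_ratio=False).logB)
            except ValueError:
                vals.append(np.nan)
        arr = np.asarray(vals)
        ok = arr[np.isfinite(arr)]
        return {
            "logB": vals,
            "n_missing": int(np.isnan(arr).sum()),
            "p5": float(np.percentile(ok, 5)) if ok.size else np.nan,
            "p50": float(np.percentile(ok, 50)) if ok.size else np.nan,
            "p95": float(np.percentile(ok, 95)) if ok.size else np.nan,
            "mean": float(ok.mean()) if ok.size else np.nan,
        }

    def randomization_test(self, candidates, observed_logB: float,
                           categorical=(), n_randomizations: int | None = None,
                           seed: int | None = None) -> dict:
        """Response-shuffling null distribution of the best free-search logB.

        p = (1 + #{null logB >= observed}) / (1 + R), so p is never zero.
        """
        cfg = self.config
        nr = cfg.n_randomizations if n_randomizations is None else n_randomizations
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        y0 = self.y.copy()
        null = []
        try:
            for _ in range(nr):
                self.y = rng.permutation(y0)
                try:
                    null.append(self.free_search(candidates, categorical).fit.logB)
                except ValueError:
                    null.append(np.nan)
        finally:
            self.y = y0
        arr = np.asarray(null)
        ok = arr[np.isfinite(arr)]
        exceed = int(np.sum(ok >= observed_logB))
        return {
            "p_value": (1 + exceed) / (1 + nr),
            "null_logB": null,
            "null_mean": float(ok.mean()) if ok.size else np.nan,
            "null_var": float(ok.var(ddof=1)) if ok.size > 1 else np.nan,
            "n_exceed": exceed,
        }


def _finalize_fit(spec, index, est, nstar, su, n_min, yv, n_complete,
                  ranges, kind="building") -> NPMRFit:
    populated = np.isfinite(est)
    ysu = yv[populated]
    esu = est[populated]
    p_bar = float(ysu.mean())
    logB = log_likelihood_ratio(ysu, esu)
    sst = float(np.sum((ysu - p_bar) ** 2))
    xr2 = 1.0 - float(np.sum((ysu - esu) ** 2)) / sst if sst > 0 else np.nan
    if esu.std() > 0 and ysu.std() > 0:
        r = float(np.corrcoef(ysu, esu)[0, 1])
    else:
        r = np.nan
    return NPMRFit(
        spec=spec, index=index, estimates=est, nstar=nstar, su=su,
        n_ave=float(nstar[populated].mean()), n_min=float(n_min),
        logB=logB, b_ave=b_ave(logB, su), xr2=xr2, r=r,
        chi2=2.0 * LN10 * logB, prevalence=p_bar, n_complete=n_complete,
        ranges=ranges, kind=kind)


# ---------------------------------------------------------------------------
# module-level convenience API (single-shot; builds a throwaway engine)

def fit(table: pd.DataFrame, spec: ModelSpec, config: NPMRConfig | None = None,
        y_col: str = "y") -> NPMRFit:
    return NPMREngine(table, y_col=y_col, config=config).fit(spec)


def loo_estimate(target_index: int, table: pd.DataFrame, spec: ModelSpec,
                 n_min: float = 0.0, y_col: str = "y"):
    """LOO estimate and neighborhood size for one row (positional index)."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    eng = NPMREngine(table, y_col=y_col)
    rows = eng.complete_rows(spec)
    w = eng.weight_matrix(spec, rows)
    np.fill_diagonal(w, 0.0)
    pos = int(np.nonzero(rows == target_index)[0][0])
    nstar = float(w[pos].sum())
    if nstar < max(n_min, np.finfo(float).tiny):
        return np.nan, nstar
    return float(w[pos] @ eng.y[rows] / nstar), nstar


def free_search(table: pd.DataFrame, candidates, config: NPMRConfig | None = None,
                categorical=(), y_col: str = "y") -> SearchResult:
    return NPMREngine(table, y_col=y_col, config=config).free_search(
        candidates, categorical)


def tune(fit_: NPMRFit, table: pd.DataFrame, config: NPMRConfig | None = None,
         y_col: str = "y") -> NPMRFit:
    return NPMREngine(table, y_col=y_col, config=config).tune(fit_)


def sensitivity(fit_: NPMRFit, table: pd.DataFrame, predictor: str,
                nudge_fraction: float | None = None, y_col: str = "y") -> float:
    """Mean |change in estimate| per proportional nudge of one predictor.

    Each complete-case row's predictor value is nudged by +/- (fraction x
    range); the row is re-estimated (leave-one-out) against the unperturbed
    rows and the absolute change, averaged over rows and both directions
    and divided by the nudge fraction, is the sensitivity Q.  Rows whose
    original or nudged estimate is missing are skipped.
    """
    if predictor not in dict(fit_.spec.tolerances):
        raise ValueError(f"{predictor!r} not a continuous predictor of the model")
    frac = NPMRConfig().nudge_fraction if nudge_fraction is None else nudge_fraction
    eng = NPMREngine(table, y_col=y_col)
    rows = eng.complete_rows(fit_.spec)
    yv = eng.y[rows]
    cols = {name: eng.table[name].to_numpy(dtype=float)[rows]
            for name, _ in fit_.spec.tolerances}
    cats = {name: eng.table[name].to_numpy()[rows] for name in fit_.spec.categorical}
    delta = frac * fit_.ranges[predictor]

    diffs = []
    for sign in (+1.0, -1.0):
        s = np.zeros((rows.size, rows.size))
        for name, sigma in fit_.spec.tolerances:
            x = cols[name]
            xt = x + sign * delta if name == predictor else x
            d = xt[:, None] - x[None, :]
            s += (d * d) / (sigma * sigma)
        w = np.exp(-0.5 * s)
        for name in fit_.spec.categorical:
            w[cats[name][:, None] != cats[name][None, :]] = 0.0
        np.fill_diagonal(w, 0.0)
        ns = w.sum(axis=1)
        ok = (ns >= fit_.n_min) & np.isfinite(fit_.estimates)
        est = np.full(rows.size, np.nan)
        est[ok] = (w[ok] @ yv) / ns[ok]
        diffs.append(np.abs(est[ok] - fit_.estimates[ok]))
    all_diffs = np.concatenate(diffs)
    if all_diffs.size == 0:
        return np.nan
    return float(all_diffs.mean() / frac)


def predict(fit_: NPMRFit, building_table: pd.DataFrame, new_rows: pd.DataFrame,
            y_col: str = "y") -> NPMRFit:
    """Estimate new rows against the building rows with the building tolerances.

    No leave-one-out here: a new row identical to a building row simply
    includes it as a neighbor.  The minimum neighborhood size is recomputed
    on the new rows (n_min_fraction x their mean n*); rows below it get a
    missing estimate.  The returned fit carries validation-set statistics.
    """
    for name in fit_.spec.predictors:
        if name not in new_rows.columns:
            raise ValueError(f"new rows missing predictor {name!r}")
    cfg = NPMRConfig()
    b = building_table.reset_index(drop=True)
    ok_b = np.ones(len(b), dtype=bool)
    for name, _ in fit_.spec.tolerances:
        ok_b &= np.isfinite(b[name].to_numpy(dtype=float))
    for name in fit_.spec.categorical:
        ok_b &= b[name].notna().to_numpy()
    ok_b &= np.isfinite(b[y_col].to_numpy(dtype=float))
    yb = b[y_col].to_numpy(dtype=float)[ok_b]

    ok_n = np.ones(len(new_rows), dtype=bool)
    for name, _ in fit_.spec.tolerances:
        ok_n &= np.isfinite(new_rows[name].to_numpy(dtype=float))
    for name in fit_.spec.categorical:
        ok_n &= new_rows[name].notna().to_numpy()
    has_y = y_col in new_rows.columns
    if has_y:
        ok_n &= np.isfinite(new_rows[y_col].to_numpy(dtype=float))
    nr = new_rows[ok_n]

    s = np.zeros((len(nr), int(ok_b.sum())))
    for name, sigma in fit_.spec.tolerances:
        xn = nr[name].to_numpy(dtype=float)
        xb = b[name].to_numpy(dtype=float)[ok_b]
        d = xn[:, None] - xb[None, :]
        s += (d * d) / (sigma * sigma)
    w = np.exp(-0.5 * s)
    for name in fit_.spec.categorical:
        cn = nr[name].to_numpy()
        cb = b[name].to_numpy()[ok_b]
        w[cn[:, None] != cb[None, :]] = 0.0
    nstar = w.sum(axis=1)
    n_min = cfg.n_min_fraction * float(nstar.mean()) if nstar.size else 0.0
    populated = nstar >= max(n_min, np.finfo(float).tiny)
    su = int(populated.sum())
    if su == 0:
        raise ValueError("no populated neighborhoods among new rows")
    est = np.full(len(nr), np.nan)
    est[populated] = (w[populated] @ yb) / nstar[populated]

    yv = (nr[y_col].to_numpy(dtype=float) if has_y
          else np.full(len(nr), np.nan))
    if has_y:
        out = _finalize_fit(fit_.spec, nr.index, est, nstar, su, n_min, yv,
                            len(nr), dict(fit_.ranges), kind="validation")
    else:
        out = NPMRFit(spec=fit_.spec, index=nr.index, estimates=est,
                      nstar=nstar, su=su, n_ave=float(nstar[populated].mean()),
                      n_min=float(n_min), logB=np.nan, b_ave=np.nan,
                      xr2=np.nan, r=np.nan, chi2=np.nan, prevalence=np.nan,
                      n_complete=len(nr), ranges=dict(fit_.ranges),
                      kind="prediction")
    return out


def bootstrap_logB(table: pd.DataFrame, spec: ModelSpec,
                   config: NPMRConfig | None = None, y_col: str = "y") -> dict:
    return NPMREngine(table, y_col=y_col, config=config).bootstrap_logB(spec)


def randomization_test(table: pd.DataFrame, candidates, observed_logB: float,
                       config: NPMRConfig | None = None, categorical=(),
                       y_col: str = "y") -> dict:
    return NPMREngine(table, y_col=y_col, config=config).randomization_test(
        candidates, observed_logB, categorical)


def response_curve(table: pd.DataFrame, fit_: NPMRFit, predictor: str,
                   grid: np.ndarray | None = None, n_points: int = 100,
                   y_col: str = "y") -> pd.DataFrame:
    """Marginal functional response of one continuous predictor.

    The estimate at each grid value weights all sample units by that
    predictor's kernel alone (the one-predictor marginal of the model);
    grid values whose neighborhood falls below the fit's n_min get NaN.
    """
    sigma = dict(fit_.spec.tolerances).get(predictor)
    if sigma is None:
        raise ValueError(f"{predictor!r} not a continuous predictor of the model")
    x = table[predictor].to_numpy(dtype=float)
    y = table[y_col].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_points)
    d = grid[:, None] - x[None, :]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    ns = w.sum(axis=1)
    est = np.full(grid.size, np.nan)
    pop = ns >= max(fit_.n_min, np.finfo(float).tiny)
    est[pop] = (w[pop] @ y) / ns[pop]
    return pd.DataFrame({predictor: grid, "estimate": est, "nstar": ns})
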