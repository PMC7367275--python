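"""Approximate Bayesian Computation over the four demographic scenarios.

Pipeline: draw parameters from per-scenario priors, simulate joint
microsatellite + mtDNA datasets (:mod:`geckoabc.coalsim`), reduce each to a
fixed summary-statistic vector, and compare with the observed vector by
Euclidean distance on MAD-normalised statistics. Model choice uses both the
direct approach (scenario proportions among the retained closest
simulations) and an Epanechnikov-weighted multinomial logistic regression
evaluated at zero stat difference; parameter estimation uses Beaumont-style
local-linear regression adjustment on prior-range-logit-transformed
parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, gaussian_kde

from .coalsim import (
    SCENARIOS,
    DemographicScenario,
    ScenarioParams,
    SimDesign,
    SimulatedDataset,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# summary statistics

#: Order of the summary-statistic vector. Clusters are 0 = North, 1 = South.
STAT_NAMES: list[str] = (
    [f"mt_{s}_c{c}" for c in (0, 1) for s in (
        "nhap", "S", "pair_mean", "pair_var", "private_S", "rarest_mean", "rarest_var")]
    + ["mt_nhap_pooled", "mt_S_pooled", "mt_within_mean", "mt_between_mean", "mt_fst"]
    + [f"ms_nall_c{c}" for c in (0, 1)] + ["ms_nall_pooled"]
    + [f"ms_het_c{c}" for c in (0, 1)] + ["ms_het_pooled", "ms_fst"]
)


def _pairwise_diff_matrix(seqs: np.ndarray) -> np.ndarray:
    return (seqs[:, None, :] != seqs[None, :, :]).sum(axis=2)


def _n_haplotypes(seqs: np.ndarray) -> int:
    if len(seqs) == 0:
        return 0
    return len(np.unique(seqs, axis=0))


def _site_base_counts(seqs: np.ndarray) -> np.ndarray:
    """(4, L) base counts per site for uint8-coded sequences."""
    return np.stack([(seqs == b).sum(axis=0) for b in range(4)])


def _wc_theta_arrays(genotypes: np.ndarray, clusters: np.ndarray) -> float:
    """Two-population Weir-Cockerham theta on complete genotype arrays."""
    from .sumstats import wc_theta

    theta = wc_theta(genotypes, clusters, 2)
    return theta if np.isfinite(theta) else 0.0


def compute_sumstats(ds: SimulatedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Summary-statistic vector and a degenerate-flag mask.

    Sequence statistics per cluster: haplotype count, segregating sites,
    mean and variance of pairwise differences, private segregating sites
    (polymorphic in the focal cluster, monomorphic in the other) and the
    mean/variance over segregating sites of the count of the rarest observed
    base. Across clusters: pooled haplotype count and S, mean within-cluster
    and between-cluster pairwise differences and the sequence
    F_ST = 1 - within/between (clamped to [-1, 1]). Microsatellites: mean
    allele number and mean unbiased genic diversity per cluster and pooled,
    and two-population Weir-Cockerham theta. Degenerate entries are imputed
    0 with the flag set.
    """
    vec = np.zeros(len(STAT_NAMES))
    degenerate = np.zeros(len(STAT_NAMES), dtype=bool)
    pos = {name: i for i, name in enumerate(STAT_NAMES)}

    def put(name: str, value: float, degen: bool = False) -> None:
        i = pos[name]
        vec[i] = 0.0 if degen or not np.isfinite(value) else value
        degenerate[i] = degen or not np.isfinite(value)

    seqs = ds.sequences
    if seqs is not None and len(seqs) > 0:
        D = _pairwise_diff_matrix(seqs)
        cl = ds.sequence_clusters
        counts_by = {c: _site_base_counts(seqs[cl == c]) for c in (0, 1)}
        seg_by = {}
        for c in (0, 1):
            sub = seqs[cl == c]
            m = len(sub)
            cnt = counts_by[c]
            seg = (cnt > 0).sum(axis=0) >= 2
            seg_by[c] = seg
            put(f"mt_nhap_c{c}", _n_haplotypes(sub), degen=m == 0)
            put(f"mt_S_c{c}", seg.sum(), degen=m == 0)
            if m >= 2:
                iu = np.triu_indices(m, 1)
                pd_vals = D[np.ix_(np.flatnonzero(cl == c), np.flatnonzero(cl == c))][iu]
                put(f"mt_pair_mean_c{c}", pd_vals.mean())
                put(f"mt_pair_var_c{c}", pd_vals.var(ddof=1) if len(pd_vals) > 1 else 0.0,
                    degen=len(pd_vals) <= 1)
            else:
                put(f"mt_pair_mean_c{c}", 0.0, degen=True)
                put(f"mt_pair_var_c{c}", 0.0, degen=True)
        for c in (0, 1):
            other = 1 - c
            mono_other = (counts_by[other] > 0).sum(axis=0) <= 1
            put(f"mt_private_S_c{c}", (seg_by[c] & mono_other).sum())
            seg = seg_by[c]
            if seg.any():
                cnt = counts_by[c][:, seg].astype(float)
                cnt[cnt == 0] = np.inf
                rare = cnt.min(axis=0)
                put(f"mt_rarest_mean_c{c}", rare.mean())
                put(f"mt_rarest_var_c{c}", rare.var(ddof=1) if seg.sum() > 1 else 0.0,
                    degen=seg.sum() <= 1)
            else:
                put(f"mt_rarest_mean_c{c}", 0.0, degen=True)
                put(f"mt_rarest_var_c{c}", 0.0, degen=True)
        put("mt_nhap_pooled", _n_haplotypes(seqs))
        pooled_cnt = _site_base_counts(seqs)
        put("mt_S_pooled", ((pooled_cnt > 0).sum(axis=0) >= 2).sum())
        within = [vec[pos[f"mt_pair_mean_c{c}"]] for c in (0, 1)
                  if not degenerate[pos[f"mt_pair_mean_c{c}"]]]
        w = float(np.mean(within)) if within else 0.0
        put("mt_within_mean", w, degen=not within)
        i0, i1 = np.flatnonzero(cl == 0), np.flatnonzero(cl == 1)
        if len(i0) and len(i1):
            between = float(D[np.ix_(i0, i1)].mean())
            put("mt_between_mean", between)
            fst = 1.0 - w / between if between > 0 else 0.0
            put("mt_fst", float(np.clip(fst, -1.0, 1.0)), degen=between == 0)
        else:
            put("mt_between_mean", 0.0, degen=True)
            put("mt_fst", 0.0, degen=True)
    else:
        for name in STAT_NAMES:
            if name.startswith("mt_"):
                put(name, 0.0, degen=True)

    geno = ds.genotypes
    if geno is not None and len(geno) > 0:
        gcl = ds.genotype_clusters
        masks = {0: gcl == 0, 1: gcl == 1, "pooled": None}
        nall: dict = {k: [] for k in masks}
        het: dict = {k: [] for k in masks}
        for l in range(geno.shape[1]):
            col = geno[:, l, :]
            vals, inv = np.unique(col, return_inverse=True)
            inv = inv.reshape(col.shape)
            for key, mask in masks.items():
                sub = inv if mask is None else inv[mask]
                if len(sub) == 0:
                    continue
                cnt = np.bincount(sub.ravel(), minlength=len(vals))
                nall[key].append(int((cnt > 0).sum()))
                n = cnt.sum()
                if n >= 2:
                    p = cnt / n
                    het[key].append(float(n / (n - 1) * (1 - (p**2).sum())))
        for c in (0, 1):
            put(f"ms_nall_c{c}", float(np.mean(nall[c])) if nall[c] else 0.0, degen=not nall[c])
            put(f"ms_het_c{c}", float(np.mean(het[c])) if het[c] else 0.0, degen=not het[c])
        put("ms_nall_pooled", float(np.mean(nall["pooled"])) if nall["pooled"] else 0.0,
            degen=not nall["pooled"])
        put("ms_het_pooled", float(np.mean(het["pooled"])) if het["pooled"] else 0.0,
            degen=not het["pooled"])
        if (gcl == 0).any() and (gcl == 1).any():
            put("ms_fst", _wc_theta_arrays(geno, gcl))
        else:
            put("ms_fst", 0.0, degen=True)
    else:
        for name in STAT_NAMES:
            if name.startswith("ms_"):
                put(name, 0.0, degen=True)
    return vec, degenerate


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorSet:
    """Per-scenario uniform prior bounds (times in years, sizes diploid).

    Defaults follow the study design: sizes U(10, 4e6); divergence time
    U(35e3, 4e5) yr for scenarios I-III and U(10, 6e4) for IV; admixture
    time U(2e3, 35e3) (I), U(501, 6e3) (II), U(10, 500) (III); admixture
    proportion fixed at 0.5; useq U(1e-9, 1e-4); kappa U(1, 30); mean
    microsatellite rate U(1e-6, 1e-2) with per-locus Gamma draws truncated
    to [1e-7, 1e-2]; P_gsm U(0.1, 0.3); sni U(1e-8, 1e-5). Scenario draws
    always satisfy t_admix < t_div.
    """

    size_bounds: tuple[float, float] = (10.0, 4_000_000.0)
    t_div_bounds: dict = field(default_factory=lambda: {
        "I": (35_000.0, 400_000.0), "II": (35_000.0, 400_000.0),
        "III": (35_000.0, 400_000.0), "IV": (10.0, 60_000.0)})
    t_admix_bounds: dict = field(default_factory=lambda: {
        "I": (2_000.0, 35_000.0), "II": (501.0, 6_000.0), "III": (10.0, 500.0)})
    useq_bounds: tuple[float, float] = (1e-9, 1e-4)
    kappa_bounds: tuple[float, float] = (1.0, 30.0)
    mu_mic_bounds: tuple[float, float] = (1e-6, 1e-2)
    p_gsm_bounds: tuple[float, float] = (0.1, 0.3)
    sni_bounds: tuple[float, float] = (1e-8, 1e-5)
    generation_time: float = 1.0

    def param_names(self, label: str) -> list[str]:
        base = ["N1", "N2", "NA", "t_div", "useq", "kappa", "mu_mic_mean", "P_gsm", "sni"]
        if label != "IV":
            base = ["N1", "N2", "N3", "N4", "NA", "t_admix", "t_div",
                    "useq", "kappa", "mu_mic_mean", "P_gsm", "sni"]
        return base

    def bounds(self, label: str, name: str) -> tuple[float, float]:
        if name in ("N1", "N2", "N3", "N4", "NA"):
            return self.size_bounds
        if name == "t_div":
            return self.t_div_bounds[label]
        if name == "t_admix":
            return self.t_admix_bounds[label]
        return {
            "useq": self.useq_bounds, "kappa": self.kappa_bounds,
            "mu_mic_mean": self.mu_mic_bounds, "P_gsm": self.p_gsm_bounds,
            "sni": self.sni_bounds,
        }[name]

    def draw(self, label: str, rng: np.random.Generator) -> ScenarioParams:
        def u(name: str) -> float:
            lo, hi = self.bounds(label, name)
            return float(rng.uniform(lo, hi))

        kwargs = dict(
            N1=u("N1"), N2=u("N2"), NA=u("NA"), t_div=u("t_div"), useq=u("useq"),
            kappa=u("kappa"), mu_mic_mean=u("mu_mic_mean"), P_gsm=u("P_gsm"),
            sni=u("sni"), generation_time=self.generation_time,
        )
        if label != "IV":
            kwargs.update(N3=u("N3"), N4=u("N4"))
            while True:
                t_admix = u("t_admix")
                if t_admix < kwargs["t_div"]:
                    break
            kwargs["t_admix"] = t_admix
        return ScenarioParams(**kwargs)


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Simulated reference table: scenario labels, parameter draws, stats."""

    scenarios: np.ndarray          # (n,) of str labels
    params: pd.DataFrame           # one column per parameter, NaN if absent
    stats: np.ndarray              # (n, n_stats)
    mad: np.ndarray                # per-stat robust scale
    stat_names: list[str] = field(default_factory=lambda: list(STAT_NAMES))

    @property
    def n(self) -> int:
        return len(self.scenarios)


def robust_scale(stats: np.ndarray) -> np.ndarray:
    """Per-stat median absolute deviation; zero-MAD columns fall back to SD,
    then to 1 so constant statistics never produce infinite distances."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = stats.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


def build_reference_table(
    priors: PriorSet,
    n_sims: int,
    design: SimDesign,
    rng: np.random.Generator,
    scenarios: tuple[str, ...] = SCENARIOS,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_sims`` draws, equally allocated across scenarios.

    Failed simulations are skipped with a log entry, never imputed.
    """
    if n_sims % len(scenarios) != 0:
        raise ValueError(f"n_sims must be divisible by {len(scenarios)} for equal allocation")
    per = n_sims // len(scenarios)
    labels, stat_rows, param_rows = [], [], []
    for label in scenarios:
        scen = DemographicScenario(label)
        for i in range(per):
            params = priors.draw(label, rng)
            try:
                ds = simulate_dataset(scen, params, design, rng)
                vec, _ = compute_sumstats(ds)
            except Exception:  # pragma: no cover - defensive
                logger.exception("simulation failed for scenario %s; row skipped", label)
                continue
            labels.append(label)
            stat_rows.append(vec)
            rec = {name: getattr(params, name) for name in priors.param_names(label)}
            param_rows.append(rec)
            if progress and (i + 1) % 1000 == 0:
                logger.info("scenario %s: %d/%d simulations", label, i + 1, per)
    stats = np.asarray(stat_rows)
    return ReferenceTable(
        np.asarray(labels), pd.DataFrame(param_rows), stats, robust_scale(stats)
    )


# ---------------------------------------------------------------------------
# rejection


@dataclass
class Retained:
    indices: np.ndarray
    distances: np.ndarray
    scenarios: np.ndarray
    params: pd.DataFrame
    stats_diff: np.ndarray  # normalised (simulated - observed)


def abc_reject(
    observed: np.ndarray,
    table: ReferenceTable,
    tolerance: float = 0.01,
    mask: np.ndarray | None = None,
) -> Retained:
    """Retain the closest ceil(tolerance * n) rows by Euclidean distance on
    MAD-normalised statistics; masked (degenerate) observed dimensions are
    dropped for every row. Ties break by row index (stable sort)."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    keep_dims = np.ones(len(table.stat_names), dtype=bool) if mask is None else ~mask
    diff = (table.stats[:, keep_dims] - observed[keep_dims]) / table.mad[keep_dims]
    dist = np.sqrt((diff**2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * table.n))
    order = np.argsort(dist, kind="stable")[:n_keep]
    full_diff = (table.stats[order] - observed) / table.mad
    return Retained(order, dist[order], table.scenarios[order],
                    table.params.iloc[order].reset_index(drop=True), full_diff)


# ---------------------------------------------------------------------------
# model choice


@dataclass
class ModelPosterior:
    probabilities: dict[str, float]
    ci: dict[str, tuple[float, float]]
    method: str
    retained: int


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel with bandwidth = max retained distance."""
    delta = distances.max()
    if delta == 0:
        return np.ones_like(distances)
    return np.clip(1.0 - (distances / delta) ** 2, 0.0, None)


def model_choice(retained: Retained, method: str = "logistic", lda: bool = True) -> ModelPosterior:
    """Scenario posterior probabilities from the retained simulations.

    ``direct``: per-scenario proportion with a normal-approximation binomial
    95% CI. ``logistic``: weighted multinomial logistic regression of the
    scenario label on the normalised stat differences, evaluated at zero
    difference; the CI comes from the asymptotic covariance of the fitted
    probabilities (delta method on the observed information). By default the
    stat differences are first projected onto linear discriminant axes
    (at most n_scenarios - 1 of them), the dimension-reduction convention of
    the reference ABC tooling, which stabilises the regression when the
    retained sample is small relative to the number of statistics; a mild
    ridge penalty guards against quasi-separation. Complete separation or a
    degenerate fit falls back to the direct approach with a warning.
    """
    if len(retained.indices) == 0:
        raise ValueError("no retained simulations")
    labels_present = [s for s in SCENARIOS if (retained.scenarios == s).any()]
    n = len(retained.scenarios)
    if method == "direct":
        probs, cis = {}, {}
        for s in SCENARIOS:
            p = float((retained.scenarios == s).mean())
            se = np.sqrt(p * (1 - p) / n)
            probs[s] = p
            cis[s] = (max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se))
        return ModelPosterior(probs, cis, "direct", n)
    if method != "logistic":
        raise ValueError(f"unknown method {method!r}")
    if len(labels_present) < 2:
        warnings.warn("fewer than 2 scenarios among retained; falling back to direct")
        return model_choice(retained, "direct")
    try:
        return _logistic_choice(retained, labels_present, lda)
    except Exception as exc:
        warnings.warn(f"logistic model choice failed ({exc}); falling back to direct")
        return model_choice(retained, "direct")


def _logistic_choice(retained: Retained, labels_present: list[str], lda: bool) -> ModelPosterior:
    from sklearn.linear_model import LogisticRegression

    X = retained.stats_diff
    y = np.array([labels_present.index(s) for s in retained.scenarios])
    w = epanechnikov_weights(retained.distances)
    pos = w > 0
    X, y, w = X[pos], y[pos], w[pos]
    if len(np.unique(y)) < 2:
        raise RuntimeError("only one scenario carries positive weight")
    x0 = np.zeros((1, X.shape[1]))
    if lda:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        proj = LinearDiscriminantAnalysis(n_components=min(len(labels_present) - 1, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X = proj.fit_transform(X, y)
        x0 = proj.transform(x0)
    clf = LogisticRegression(penalty="l2", C=10.0, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y, sample_weight=w)
    p_rows = clf.predict_proba(X)
    p0 = clf.predict_proba(x0)[0]
    if not np.all(np.isfinite(p0)):
        raise RuntimeError("non-finite fitted probabilities")
    K = len(labels_present)
    d = X.shape[1] + 1  # intercept + stats
    Z = np.hstack([np.ones((len(X), 1)), X])
    # observed information in the reference-class parameterisation (class K-1 ref)
    dim = (K - 1) * d
    info = np.zeros((dim, dim))
    for a in range(K - 1):
        for b in range(K - 1):
            pa, pb = p_rows[:, a], p_rows[:, b]
            wvec = w * (pa * (1 - pa)) if a == b else w * (-pa * pb)
            block = (Z * wvec[:, None]).T @ Z
            info[a * d:(a + 1) * d, b * d:(b + 1) * d] = block
    cov = np.linalg.pinv(info)
    z0 = np.concatenate([[1.0], x0.ravel()])
    # gradient of p_a(x0) wrt beta_{b,:} is (delta_ab p_a - p_a p_b) z0
    grad = np.zeros((K, dim))
    for a in range(K):
        for b in range(K - 1):
            coef = (1.0 if a == b else 0.0) * p0[a] - p0[a] * p0[b]
            grad[a, b * d:(b + 1) * d] = coef * z0
    var = np.einsum("ai,ij,aj->a", grad, cov, grad)
    se = np.sqrt(np.clip(var, 0.0, None))
    if np.any(se > 10):
        raise RuntimeError("separation suspected: unstable probability SEs")
    probs = {s: 0.0 for s in SCENARIOS}
    cis = {s: (0.0, 0.0) for s in SCENARIOS}
    for i, s in enumerate(labels_present):
        probs[s] = float(p0[i])
        cis[s] = (float(max(0.0, p0[i] - 1.96 * se[i])),
                  float(min(1.0, p0[i] + 1.96 * se[i])))
    return ModelPosterior(probs, cis, "logistic", len(retained.scenarios))


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class ParameterPosterior:
    estimates: pd.DataFrame  # index: parameter; columns: mode, q025, q975
    adjusted: pd.DataFrame   # regression-adjusted posterior sample
    weights: np.ndarray
    method: str


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


def estimate_parameters(
    retained: Retained,
    priors: PriorSet,
    scenario: str,
    kde_grid: int = 512,
) -> ParameterPosterior:
    """Beaumont-style local-linear adjusted posterior for one scenario.

    Retained rows of the requested scenario are logit-transformed to their
    prior range, regressed on the normalised stat differences with
    Epanechnikov weights, adjusted to zero difference, back-transformed and
    summarised by a weighted-KDE mode and weighted 2.5/97.5% quantiles
    (guaranteed inside the prior bounds by the back-transform). A singular
    design falls back to the unadjusted rejection posterior with a warning.
    """
    sel = retained.scenarios == scenario
    if sel.sum() < 50:
        raise ValueError(f"need >= 50 retained rows for scenario {scenario}, have {int(sel.sum())}")
    names = priors.param_names(scenario)
    theta = retained.params.loc[sel, names].to_numpy(dtype=float)
    X = retained.stats_diff[sel]
    w = epanechnikov_weights(retained.distances[sel])
    if w.sum() == 0:
        w = np.ones_like(w)
    bounds = np.array([priors.bounds(scenario, nm) for nm in names])
    lo, hi = bounds[:, 0], bounds[:, 1]
    eps = 1e-9
    frac = np.clip((theta - lo) / (hi - lo), eps, 1 - eps)
    z = np.log(frac / (1 - frac))
    Z = np.hstack([np.ones((len(X), 1)), X])
    sw = np.sqrt(w)
    method = "loclinear"
    try:
        beta, *_ = np.linalg.lstsq(Z * sw[:, None], z * sw[:, None], rcond=None)
        fitted0 = beta[0]  # prediction at zero stat difference
        resid = z - Z @ beta
        z_adj = fitted0[None, :] + resid
        if not np.all(np.isfinite(z_adj)):
            raise np.linalg.LinAlgError("non-finite adjustment")
    except np.linalg.LinAlgError:
        warnings.warn("singular regression design; returning rejection-only posterior")
        z_adj = z
        method = "rejection"
    adj = lo + (hi - lo) / (1.0 + np.exp(-z_adj))
    rows = []
    for i, nm in enumerate(names):
        x = adj[:, i]
        if np.ptp(x) > 0:
            try:
                kde = gaussian_kde(x, weights=w)
                grid = np.linspace(x.min(), x.max(), kde_grid)
                mode = float(grid[np.argmax(kde(grid))])
            except np.linalg.LinAlgError:
                mode = float(np.median(x))
        else:
            mode = float(x[0])
        rows.append({
            "parameter": nm, "mode": mode,
            "q025": _weighted_quantile(x, w, 0.025),
            "q975": _weighted_quantile(x, w, 0.975),
        })
    est = pd.DataFrame(rows).set_index("parameter")
    return ParameterPosterior(est, pd.DataFrame(adj, columns=names), w, method)


# ---------------------------------------------------------------------------
# PCA prior check


@dataclass
class PriorCheck:
    percentile: float
    flagged: bool
    dropped_stats: list[str]
    projection: np.ndarray


def pca_prior_check(table: ReferenceTable, observed: np.ndarray) -> PriorCheck:
    """Project the observed vector onto the table's first two principal axes
    and report its Mahalanobis percentile in that plane (flag above 99%)."""
    from sklearn.decomposition import PCA

    if table.n < 100:
        raise ValueError("prior check needs a table of >= 100 rows")
    scaled = (table.stats - table.stats.mean(axis=0))
    sd = table.stats.std(axis=0)
    keep = sd > 1e-10 * (np.abs(table.stats.mean(axis=0)) + 1.0)
    dropped = [n for n, k in zip(table.stat_names, keep) if not k]
    if dropped:
        logger.info("constant statistics dropped before PCA: %s", dropped)
    scaled = scaled[:, keep] / sd[keep]
    pca = PCA(n_components=2)
    scores = pca.fit_transform(scaled)
    obs_scaled = (observed[keep] - table.stats.mean(axis=0)[keep]) / sd[keep]
    obs_score = pca.transform(obs_scaled[None, :])[0]
    cov = np.cov(scores.T)
    delta = obs_score - scores.mean(axis=0)
    d2 = float(delta @ np.linalg.solve(cov, delta))
    pct = float(chi2.cdf(d2, df=2) * 100)
    return PriorCheck(pct, pct > 99.0, dropped, obs_score)
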