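"""Differential expression: TMM normalization, negative-binomial GLMs,
likelihood-ratio tests, BH correction, the four-step intersection procedure,
and single-pattern-expression (SPE) calling.

The model for gene g, sample s is

    y_gs ~ NB(mu_gs, phi),   var = mu + phi * mu^2,
    log mu_gs = offset_s + x_s' beta,

with offsets the log effective (TMM-scaled) library sizes and a common
dispersion phi estimated by maximizing the Cox-Reid adjusted profile
likelihood summed over a gene subsample.  Nested models are compared with a
likelihood-ratio test against chi-squared.

The stepwise procedure isolates genes whose allele effect is attributable to
the introgressed region alone:

  I.  fit allele + NIL + allele x NIL on all 7 samples; record genes with a
      BH-significant interaction, and genes with a BH-significant NIL main
      effect (tested with the interaction absent);
  II. fit allele-only within each NIL pair; record per-pair DE sets;
  III. per pair, remove from the step II set any gene significant for NIL or
      interaction in step I;
  IV. intersect the two step III sets; direction (Up/Down in F288 relative to
      F271) must agree across pairs, else the gene is flagged discordant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln
from scipy.stats import rankdata

from .data_io import CountMatrix, SampleDesign, validate_design

LN2 = np.log(2.0)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TMM normalization


@dataclass
class NormalizationFactors:
    sample_ids: list[str]
    factors: np.ndarray  # geometric mean 1
    library_sizes: np.ndarray

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.factors * self.library_sizes


def _tmm_pair(y_s, y_r, N_s, N_r, logratio_trim=0.3, sum_trim=0.05):
    """Doubly trimmed, inverse-variance-weighted mean of gene-wise log2 ratios
    of sample s against reference r (genes zero in either sample excluded)."""
    keep = (y_s > 0) & (y_r > 0)
    y_s, y_r = y_s[keep].astype(float), y_r[keep].astype(float)
    if y_s.size == 0:
        return 0.0
    M = np.log2((y_s / N_s) / (y_r / N_r))
    A = 0.5 * np.log2((y_s / N_s) * (y_r / N_r))
    v = (N_s - y_s) / (N_s * y_s) + (N_r - y_r) / (N_r * y_r)
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = M.size
    loM, hiM = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    loA, hiA = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rM, rA = rankdata(M), rankdata(A)
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        return 0.0
    return float(np.sum(M[keep2] / v[keep2]) / np.sum(1.0 / v[keep2]))


def tmm_factors(cm: CountMatrix, reference: str | None = None) -> NormalizationFactors:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample defaults to the one whose 75th percentile of
    count/library-size is closest to the across-sample mean.
    """
    counts = cm.counts
    lib = cm.library_sizes.astype(float)
    if (lib == 0).any():
        bad = cm.sample_ids[int(np.argmin(lib))]
        raise ModelError(f"sample {bad!r} has all-zero counts")
    if reference is None:
        f75 = np.array([np.quantile(counts[:, s] / lib[s], 0.75)
                        for s in range(counts.shape[1])])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = cm.sample_ids.index(reference)
    logf = np.array([
        0.0 if s == ref else _tmm_pair(counts[:, s], counts[:, ref], lib[s], lib[ref])
        for s in range(counts.shape[1])
    ])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(list(cm.sample_ids), factors, cm.library_sizes)


# ---------------------------------------------------------------------------
# NB GLM


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Exact NB log-likelihood (var = mu + phi mu^2); phi = 0 is Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, None)
    if phi == 0.0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Residual deviance: 2 * (saturated loglik - model loglik)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, None)
    yp = np.clip(y, 1e-10, None)
    if phi == 0.0:
        dev = 2.0 * np.sum(y * np.log(yp / mu) - (y - mu))
    else:
        dev = 2.0 * np.sum(
            y * np.log(yp / mu) - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        )
    return float(max(dev, 0.0))


@dataclass
class NBFit:
    beta: np.ndarray  # natural-log scale
    phi: float
    mu: np.ndarray
    deviance: float
    loglik: float
    converged: bool
    n_iter: int
    cr_logdet: float = 0.0  # log det(X' W X) at the fit, for Cox-Reid APL

    def log2fc(self, index: int) -> float:
        return float(self.beta[index] / LN2)


def fit_nb_glm(y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi: float,
               tol: float = 1e-8, max_iter: int = 100) -> NBFit:
    """Fit an NB GLM with log link at fixed dispersion by IRLS.

    Converged when the relative deviance change is below ``tol`` (or the
    deviance itself is negligible); non-convergence is flagged on the result,
    never silently dropped.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n != y.size:
        raise ModelError("design matrix rows do not match observations")
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("design matrix not full rank on available samples")
    # initialize from a linearized fit
    eta0 = np.log(np.clip(y, 0.5, None)) - offsets
    beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    dev = np.inf
    converged = False
    W = np.ones(n)
    for it in range(1, max_iter + 1):
        eta = np.clip(offsets + X @ beta, -50.0, 50.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi * mu)
        z = (eta - offsets) + (y - mu) / mu
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        mu_new = np.exp(np.clip(offsets + X @ beta_new, -50.0, 50.0))
        dev_new = nb_deviance(y, mu_new, phi)
        beta = beta_new
        if dev_new < 1e-12 or abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    eta = np.clip(offsets + X @ beta, -50.0, 50.0)
    mu = np.exp(eta)
    W = mu / (1.0 + phi * mu)
    XtWX = (X.T * W) @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    return NBFit(
        beta=beta, phi=phi, mu=mu, deviance=nb_deviance(y, mu, phi),
        loglik=nb_loglik(y, mu, phi), converged=converged, n_iter=it,
        cr_logdet=float(logdet if sign > 0 else -np.inf),
    )


def lrt(full: NBFit, reduced: NBFit, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic (reduced deviance - full deviance) against
    chi-squared(df); tiny negative statistics from convergence noise are
    clamped to 0, larger ones indicate a non-nested or failed fit."""
    stat = reduced.deviance - full.deviance
    floor = -1e-8 * max(1.0, reduced.deviance)
    if stat < floor:
        raise ModelError(f"negative LRT statistic {stat:.3g}: models not nested or not converged")
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ModelError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# dispersion


def fit_dispersion(counts: np.ndarray, X: np.ndarray, offsets: np.ndarray,
                   n_subsample: int = 200, cox_reid: bool = True,
                   bounds: tuple[float, float] = (1e-6, 10.0)) -> float:
    """Common dispersion maximizing the summed NB profile likelihood.

    The default applies the Cox-Reid adjustment (-0.5 log det X'WX per gene),
    which removes most of the downward bias from estimating per-gene
    coefficients.  A deterministic, mean-stratified gene subsample keeps the
    cost flat in the number of genes.
    """
    counts = np.atleast_2d(counts)
    n_genes, n_samples = counts.shape
    if n_samples - X.shape[1] < 1:
        raise ModelError("no residual degrees of freedom to estimate dispersion")
    if (counts.sum(axis=1) == 0).any():
        raise ModelError("all-zero gene rows must be removed before dispersion estimation")
    if n_genes > n_subsample:
        order = np.argsort(counts.mean(axis=1), kind="stable")
        pick = order[np.linspace(0, n_genes - 1, n_subsample).astype(int)]
        counts = counts[pick]

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        total = 0.0
        for y in counts:
            fit = fit_nb_glm(y, X, offsets, phi)
            total += fit.loglik - (0.5 * fit.cr_logdet if cox_reid else 0.0)
        return -total

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_apl, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# design matrices


def design_matrix_full(design: list[SampleDesign]) -> np.ndarray:
    """Treatment coding, F271/pair-1 baseline: [1, allele_F288, nil_2, interaction]."""
    a = np.array([1.0 if d.allele == "F288" else 0.0 for d in design])
    n = np.array([1.0 if d.nil_pair == 2 else 0.0 for d in design])
    return np.column_stack([np.ones(len(design)), a, n, a * n])


# ---------------------------------------------------------------------------
# stepwise procedure


@dataclass
class DETestResult:
    gene_id: str
    term: str  # interaction / nil / allele_pair1 / allele_pair2
    log2fc: float
    statistic: float
    df: int
    p: float
    p_adj: float = np.nan


@dataclass
class StepwiseSets:
    step1_interaction_sig: set[str]
    step1_nil_sig: set[str]
    step2: dict[int, set[str]]  # pair -> genes
    step3: dict[int, set[str]]
    final_common: set[str]
    direction: dict[str, str] = field(default_factory=dict)  # Up/Down/discordant
    tests: list[DETestResult] = field(default_factory=list)

    def validate(self) -> None:
        for pair in (1, 2):
            if not self.step3[pair] <= self.step2[pair]:
                raise ModelError(f"step3 set for pair {pair} not within step2")
        if self.final_common != self.step3[1] & self.step3[2]:
            raise ModelError("final set is not the step3 intersection")
        if self.final_common & (self.step1_interaction_sig | self.step1_nil_sig):
            raise ModelError("final set overlaps step-I NIL/interaction genes")

    @property
    def up(self) -> set[str]:
        return {g for g in self.final_common if self.direction.get(g) == "Up"}

    @property
    def down(self) -> set[str]:
        return {g for g in self.final_common if self.direction.get(g) == "Down"}


def stepwise_sets_from_significance(
    step1_interaction_sig: set[str],
    step1_nil_sig: set[str],
    step2: dict[int, set[str]],
    step1_tested: set[str] | None = None,
) -> StepwiseSets:
    """The pure set algebra of steps III and IV, given per-step significance.

    Step III intersects each pair's step II set with the step-I genes showing
    no significant NIL or interaction effect; a gene never tested in step I
    cannot be cleared, so when ``step1_tested`` is given, genes outside it are
    removed too.  ``run_stepwise`` tests every gene in every step, where the
    two readings coincide.
    """
    screened = step1_interaction_sig | step1_nil_sig
    if step1_tested is None:
        step3 = {pair: genes - screened for pair, genes in step2.items()}
    else:
        cleared = step1_tested - screened
        step3 = {pair: genes & cleared for pair, genes in step2.items()}
    final = step3[1] & step3[2]
    out = StepwiseSets(
        step1_interaction_sig=set(step1_interaction_sig),
        step1_nil_sig=set(step1_nil_sig),
        step2={p: set(g) for p, g in step2.items()},
        step3=step3,
        final_common=final,
    )
    out.validate()
    return out


def run_stepwise(cm: CountMatrix, design: list[SampleDesign], alpha: float = 0.05,
                 phi: float | None = None,
                 norm: NormalizationFactors | None = None) -> StepwiseSets:
    """The four-step intersection procedure on NB GLM likelihood-ratio tests.

    BH correction is applied within each term's family separately (interaction,
    NIL, and each pair's allele family).  Genes with zero total count are
    dropped before fitting.
    """
    validate_design(design)
    cm = cm.subset_samples([d.sample_id for d in design])
    keep = cm.counts.sum(axis=1) > 0
    counts = cm.counts[keep]
    genes = [g for g, k in zip(cm.gene_ids, keep) if k]

    if norm is None:
        norm = tmm_factors(cm)
    offsets = np.log(norm.effective_library_sizes)

    X_full = design_matrix_full(design)
    X_noint = X_full[:, :3]
    X_allele = X_full[:, :2]
    if phi is None:
        phi = fit_dispersion(counts, X_full, offsets)

    pair_cols = {p: [i for i, d in enumerate(design) if d.nil_pair == p] for p in (1, 2)}
    pair_X = {p: X_allele[cols] for p, cols in pair_cols.items()}
    pair_off = {p: offsets[cols] for p, cols in pair_cols.items()}

    tests: list[DETestResult] = []
    pvals = {"interaction": [], "nil": [], "allele_pair1": [], "allele_pair2": []}
    fc_pair = {1: {}, 2: {}}
    for g, y in zip(genes, counts):
        fit_full = fit_nb_glm(y, X_full, offsets, phi)
        fit_noint = fit_nb_glm(y, X_noint, offsets, phi)
        fit_allele = fit_nb_glm(y, X_allele, offsets, phi)
        s_int, p_int = lrt(fit_full, fit_noint, 1)
        s_nil, p_nil = lrt(fit_noint, fit_allele, 1)
        tests.append(DETestResult(g, "interaction", fit_full.log2fc(3), s_int, 1, p_int))
        tests.append(DETestResult(g, "nil", fit_noint.log2fc(2), s_nil, 1, p_nil))
        pvals["interaction"].append(p_int)
        pvals["nil"].append(p_nil)
        for pair in (1, 2):
            yq = y[pair_cols[pair]]
            fit_a = fit_nb_glm(yq, pair_X[pair], pair_off[pair], phi)
            fit_0 = fit_nb_glm(yq, pair_X[pair][:, :1], pair_off[pair], phi)
            s_a, p_a = lrt(fit_a, fit_0, 1)
            fc = fit_a.log2fc(1)
            fc_pair[pair][g] = fc
            tests.append(DETestResult(g, f"allele_pair{pair}", fc, s_a, 1, p_a))
            pvals[f"allele_pair{pair}"].append(p_a)

    adj = {term: bh_adjust(np.array(ps)) for term, ps in pvals.items()}
    idx = {term: 0 for term in adj}
    for t in tests:
        t.p_adj = float(adj[t.term][idx[t.term]])
        idx[t.term] += 1

    sig = {term: {genes[i] for i in np.flatnonzero(adj[term] <= alpha)} for term in adj}
    sets = stepwise_sets_from_significance(
        sig["interaction"], sig["nil"],
        {1: sig["allele_pair1"], 2: sig["allele_pair2"]},
    )
    for g in sets.final_common:
        s1, s2 = np.sign(fc_pair[1][g]), np.sign(fc_pair[2][g])
        if s1 == s2 and s1 != 0:
            sets.direction[g] = "Up" if s1 > 0 else "Down"
        else:
            sets.direction[g] = "discordant"
    sets.tests = tests
    return sets


# ---------------------------------------------------------------------------
# SPE


@dataclass
class SPEFlag:
    gene_id: str
    pattern: str  # SPE_F288 / SPE_F271 / none
    max_silent: int
    min_expressed: int


def detect_spe(cm: CountMatrix, design: list[SampleDesign],
               max_silent: int = 0, min_expressed: int = 1) -> list[SPEFlag]:
    """SPE_F288: every F271 sample (both pairs) has count <= max_silent and
    every F288 sample has count >= min_expressed; SPE_F271 symmetric."""
    validate_design(design)
    cm = cm.subset_samples([d.sample_id for d in design])
    f271 = [i for i, d in enumerate(design) if d.allele == "F271"]
    f288 = [i for i, d in enumerate(design) if d.allele == "F288"]
    flags = []
    for g, y in zip(cm.gene_ids, cm.counts):
        y271, y288 = y[f271], y[f288]
        if y271.max() <= max_silent and y288.min() >= min_expressed:
            pattern = "SPE_F288"
        elif y288.max() <= max_silent and y271.min() >= min_expressed:
            pattern = "SPE_F271"
        else:
            pattern = "none"
        flags.append(SPEFlag(
            gene_id=g, pattern=pattern,
            max_silent=int(y271.max() if pattern == "SPE_F288" else y288.max()),
            min_expressed=int(y288.min() if pattern == "SPE_F288" else y271.min()),
        ))
    return flags
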