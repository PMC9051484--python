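"""Independent oracles used by the tests.

The RAM oracle builds, for a whole twin pair, the full structural system of
latent and observed variables (path matrix ``A``, exogenous covariance
``S``, filter ``F``) and computes the implied observed covariance by the
standard reticular-action-model identity

    Sigma = F (I - A)^-1 S (I - A)^-T F^T.

Every latent source is explicit (factor sources, chain innovations,
occasion residuals, for both twins) with cross-twin correlations fixed by
zygosity, so this enumerates all tracing paths without using the package's
block-algebra construction.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

R_A = {"MZ": 1.0, "DZ": 0.5}


class _Ram:
    def __init__(self):
        self.names: list[str] = []
        self.paths: list[tuple[str, str, float]] = []  # (src, dst, coeff)
        self.covs: list[tuple[str, str, float]] = []  # symmetric S entries

    def node(self, name: str) -> str:
        if name not in self.names:
            self.names.append(name)
        return name

    def path(self, src: str, dst: str, coeff: float) -> None:
        self.paths.append((self.node(src), self.node(dst), coeff))

    def cov(self, a: str, b: str, value: float) -> None:
        self.covs.append((self.node(a), self.node(b), value))

    def sigma(self, observed: list[str]) -> np.ndarray:
        n = len(self.names)
        idx = {nm: i for i, nm in enumerate(self.names)}
        amat = np.zeros((n, n))
        for src, dst, c in self.paths:
            amat[idx[dst], idx[src]] += c
        smat = np.zeros((n, n))
        for a, b, v in self.covs:
            smat[idx[a], idx[b]] += v
            if a != b:
                smat[idx[b], idx[a]] += v
        total = np.linalg.solve(np.eye(n) - amat, smat) @ np.linalg.inv(np.eye(n) - amat).T
        rows = [idx[o] for o in observed]
        return total[np.ix_(rows, rows)]


def _source(ram: _Ram, base: str, comp: str, r_a: float) -> None:
    """Unit-variance latent source for both twins with cross-twin covariance."""
    for tw in (1, 2):
        ram.cov(f"{base}@{tw}", f"{base}@{tw}", 1.0)
    cross = {"A": r_a, "C": 1.0, "E": 0.0}[comp]
    if cross:
        ram.cov(f"{base}@1", f"{base}@2", cross)


def ram_pair_covariance(model, theta, zygosity: str) -> np.ndarray:
    """Implied pair covariance by full RAM enumeration (independent route)."""
    p = model.param_dict(np.asarray(theta, dtype=float))
    t = model.n_vars
    kind = model.meta["kind"]
    comps = model.meta["components"]
    r_a = R_A[zygosity]
    ram = _Ram()
    observed = [f"y{i + 1}@{tw}" for tw in (1, 2) for i in range(t)]
    for o in observed:
        ram.node(o)

    for tw in (1, 2):
        if kind in ("univariate", "cf"):
            for c in comps:
                for kcol in range(t):
                    name = f"F_{c}{kcol + 1}"
                    for i in range(kcol, t):
                        key = c.lower() if kind == "univariate" else f"{c.lower()}_{i + 1}{kcol + 1}"
                        ram.path(f"{name}@{tw}", f"y{i + 1}@{tw}", p[key])
        elif kind == "ar":
            res_struct = model.meta.get("residual_structure", "free")
            for c in comps:
                lc = c.lower()
                for i in range(t):
                    ram.path(f"z_{c}{i + 1}@{tw}", f"g_{c}{i + 1}@{tw}", p[f"{lc}_inn_{i + 1}"])
                    ram.path(f"g_{c}{i + 1}@{tw}", f"y{i + 1}@{tw}", 1.0)
                    if i:
                        ram.path(f"g_{c}{i}@{tw}", f"g_{c}{i + 1}@{tw}", p[f"beta_{lc}_{i + 1}"])
            for i in range(t):
                key = "e_res" if res_struct == "equal" else f"e_res_{i + 1}"
                ram.path(f"r_E{i + 1}@{tw}", f"y{i + 1}@{tw}", p[key])
                if model.meta.get("genetic_residuals"):
                    akey = "a_res" if res_struct == "equal" else f"a_res_{i + 1}"
                    ram.path(f"r_A{i + 1}@{tw}", f"y{i + 1}@{tw}", p[akey])
        elif kind == "cp":
            for k in range(model.meta["n_factors"]):
                used = 0.0
                for c in ("A", "C"):
                    if f"fac{k + 1}_{c.lower()}" in p and c in comps:
                        coeff = p[f"fac{k + 1}_{c.lower()}"]
                        ram.path(f"S_{c}{k + 1}@{tw}", f"Fac{k + 1}@{tw}", coeff)
                        used += coeff**2
                ram.path(f"S_E{k + 1}@{tw}", f"Fac{k + 1}@{tw}", np.sqrt(max(1.0 - used, 0.0)))
                for i in range(t):
                    ram.path(f"Fac{k + 1}@{tw}", f"y{i + 1}@{tw}", p[f"lam{k + 1}_{i + 1}"])
            for c in comps:
                for i in range(t):
                    ram.path(f"r_{c}{i + 1}@{tw}", f"y{i + 1}@{tw}", p[f"{c.lower()}_res_{i + 1}"])
        elif kind == "ip":
            for c in comps:
                for i in range(t):
                    # S_* prefix marks the common factor as an exogenous source
                    ram.path(f"S_{c}0@{tw}", f"y{i + 1}@{tw}", p[f"lam_{c.lower()}{i + 1}"])
                    ram.path(f"r_{c}{i + 1}@{tw}", f"y{i + 1}@{tw}", p[f"{c.lower()}_res_{i + 1}"])
        else:
            raise ValueError(f"no RAM builder for kind {kind!r}")

    # exogenous sources with zygosity-specific cross-twin covariances
    for name in list(ram.names):
        if name.endswith("@1") and not name.startswith("y") and not name.startswith("g_") and not name.startswith("Fac"):
            base = name[:-2]
            comp = {"F": base[2], "z": base[2], "r": base[2], "S": base[2]}[base[0]]
            _source(ram, base, comp, r_a)
    return ram.sigma(observed)


def mvn_loglik_oracle(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """-2 log-likelihood summed row by row via scipy's density (independent)."""
    total = 0.0
    for row in np.atleast_2d(x):
        obs = ~np.isnan(row)
        total += -2.0 * stats.multivariate_normal.logpdf(
            row[obs], mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
        )
    return total


def polyserial_grid_oracle(x: np.ndarray, codes: np.ndarray, step: float = 0.001) -> float:
    """Brute-force grid maximizer of the polyserial likelihood."""
    n = len(x)
    counts = np.bincount(codes)
    tau = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(counts)[:-1] / n), [np.inf]])
    z = (x - x.mean()) / x.std()
    grid = np.arange(-0.999, 0.999 + step / 2, step)
    best_rho, best_ll = 0.0, -np.inf
    for rho in grid:
        w = np.sqrt(1 - rho**2)
        prob = stats.norm.cdf((tau[codes + 1] - rho * z) / w) - stats.norm.cdf(
            (tau[codes] - rho * z) / w
        )
        if np.any(prob <= 0):
            continue
        ll = float(np.sum(np.log(prob)))
        if ll > best_ll:
            best_rho, best_ll = float(rho), ll
    return best_rho
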