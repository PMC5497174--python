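"""Joint model of longitudinal cognition and discrete-time events.

The longitudinal outcome is the mean standardised cognitive score, modelled
as a linear mixed model with person-level random intercept and slope on
time-in-study.  The event of interest is incident dementia per two-year
epoch, whose log-odds depend on covariates plus the current value m(t) and
slope m'(t) of the subject-specific latent trajectory (shared random
effects).  Because both panel attrition and death select on the latent
trajectory, censoring is not ignorable for the longitudinal+dementia
likelihood alone; auxiliary discrete-time attrition and survival submodels
sharing the same random effects are therefore included by default.

Estimation maximises the observed-data likelihood by an EM algorithm.  The
key computational device: conditionally on the longitudinal data the random
effects are exactly Gaussian, so the marginal likelihood factorises as

    L_i = L_i^LMM x  E_{b ~ N(bhat_i, V_i)}[ L_i^events(b) ]

with the first factor in closed form and the expectation evaluated by
Gauss-Hermite quadrature centred on the exact per-person posterior
(adaptive by construction).  E-step posteriors are the tilted node weights;
M-steps are closed-form (variance components) or single damped Newton
updates (fixed effects, event coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from .cohort import BASE_YEAR
from .trends import ANALYSIS_WAVES, RF_COLUMNS, TrendEstimate, _ParamsMixin, \
    build_person_epochs, trend_from_coef

LONG_COLUMNS = ["const", "ae", "ae2", "time", "time2", "female", "year_c",
                "educ_mid", "educ_high", "midlife_obesity",
                "midlife_hypertension", "midlife_diabetes"]

EVENT_RF = ["smoking", "inactivity", "current_hypertension"]


def _gh_nodes(k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D product Gauss-Hermite rule for expectations under N(0, I2)."""
    x, w = np.polynomial.hermite.hermgauss(k)
    z = np.sqrt(2.0) * x
    lw = np.log(w) - 0.5 * np.log(np.pi)
    Z1, Z2 = np.meshgrid(z, z, indexing="ij")
    LW1, LW2 = np.meshgrid(lw, lw, indexing="ij")
    return np.column_stack([Z1.ravel(), Z2.ravel()]), (LW1 + LW2).ravel()


def _long_design(df: pd.DataFrame) -> np.ndarray:
    ae = (df["entry_age"].to_numpy() - 65.0) / 10.0
    t = df["time"].to_numpy(dtype=float)
    female = (df["sex"] == "f").to_numpy(dtype=float)
    educ = df["education"].to_numpy()
    X = np.column_stack([
        np.ones(len(df)), ae, ae**2, t, t**2, female,
        df["year"].to_numpy(dtype=float) - BASE_YEAR,
        (educ == "intermediate").astype(float), (educ == "higher").astype(float),
        df["midlife_obesity"].to_numpy(dtype=float),
        df["midlife_hypertension"].to_numpy(dtype=float),
        df["midlife_diabetes"].to_numpy(dtype=float),
    ])
    return X


def _long_design_at(entry_age, t, female, year, educ_mid, educ_high, ob, htn, db):
    """Longitudinal design and its time-derivative at arbitrary times."""
    ae = (np.asarray(entry_age, dtype=float) - 65.0) / 10.0
    t = np.asarray(t, dtype=float)
    one = np.ones_like(t)
    X = np.column_stack([one, ae, ae**2, t, t**2, female, year - BASE_YEAR,
                         educ_mid, educ_high, ob, htn, db])
    # derivative w.r.t. time-in-study, holding calendar year fixed (the
    # trajectory slope: ageing-related decline, not secular drift)
    dX = np.zeros_like(X)
    dX[:, 3] = 1.0
    dX[:, 4] = 2.0 * t
    return X, dX


def fit_linear_mixed(X: np.ndarray, y: np.ndarray, pidx: np.ndarray,
                     t: np.ndarray, n_iter: int = 200, tol: float = 1e-9):
    """ML fit of the random-intercept / random-slope linear mixed model
    y = X beta + b0 + b1 t + e by EM (closed-form steps).

    Returns (beta, sigma2, Sigma, loglik).  Serves as the two-stage
    initialiser of the joint model and is cross-checkable against a
    generic REML/ML mixed-model routine.
    """
    n = int(pidx.max()) + 1
    ZtZ = np.zeros((n, 2, 2))
    ZtZ[:, 0, 0] = np.bincount(pidx, minlength=n)
    ZtZ[:, 0, 1] = ZtZ[:, 1, 0] = np.bincount(pidx, weights=t, minlength=n)
    ZtZ[:, 1, 1] = np.bincount(pidx, weights=t**2, minlength=n)
    XtX = X.T @ X
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma2 = float(np.var(y - X @ beta)) * 0.6
    Sigma = np.array([[0.25, 0.0], [0.0, 0.002]])
    ll_prev = -np.inf
    ll = -np.inf
    mask = ZtZ[:, 0, 0] > 0
    for _ in range(n_iter):
        r = y - X @ beta
        Zr = np.column_stack([np.bincount(pidx, weights=r, minlength=n),
                              np.bincount(pidx, weights=r * t, minlength=n)])
        SSR = np.bincount(pidx, weights=r**2, minlength=n)
        Sinv, detS = _inv2(Sigma[None, :, :])
        V, detP = _inv2(Sinv + ZtZ / sigma2)
        bhat = np.einsum("nij,nj->ni", V, Zr) / sigma2
        quad = (SSR - np.einsum("ni,nij,nj->n", Zr, V, Zr) / sigma2) / sigma2
        ll = float(-0.5 * (ZtZ[:, 0, 0] * np.log(2 * np.pi * sigma2)
                           + np.log(detS[0] * detP) + quad)[mask].sum())
        Ebb = V + np.einsum("ni,nj->nij", bhat, bhat)
        Sigma = Ebb[mask].mean(axis=0)
        pred_b = bhat[pidx, 0] + bhat[pidx, 1] * t
        beta = np.linalg.solve(XtX, X.T @ (y - pred_b))
        resid = y - X @ beta - pred_b
        tr = np.einsum("nij,nij->n", ZtZ, V)
        sigma2 = float((resid @ resid + tr[mask].sum()) / len(y))
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    return beta, sigma2, Sigma, ll


@dataclass
class _EventBlock:
    """One discrete-time submodel sharing the random effects."""

    name: str
    person: np.ndarray  # index into the person table
    d: np.ndarray  # binary outcome
    W: np.ndarray  # fixed design (R, k)
    Xm: np.ndarray  # longitudinal design at event time (R, p) -> m(t) fixed part
    Xs: np.ndarray  # its time-derivative (R, p) -> m'(t) fixed part
    t: np.ndarray  # time-in-study at event time (b1 multiplier in m)
    colnames: list

    @property
    def k(self) -> int:
        return self.W.shape[1]


def _chol2(V: np.ndarray) -> np.ndarray:
    """Cholesky of a stack of 2x2 SPD matrices."""
    l11 = np.sqrt(V[:, 0, 0])
    l21 = V[:, 1, 0] / l11
    l22 = np.sqrt(np.maximum(V[:, 1, 1] - l21**2, 1e-12))
    out = np.zeros_like(V)
    out[:, 0, 0], out[:, 1, 0], out[:, 1, 1] = l11, l21, l22
    return out


def _inv2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1] / det
    inv[:, 1, 1] = M[:, 0, 0] / det
    inv[:, 0, 1] = -M[:, 0, 1] / det
    inv[:, 1, 0] = -M[:, 1, 0] / det
    return inv, det


class JointCognitionEventModel(_ParamsMixin):
    """Shared-random-effects joint model (longitudinal + dementia onset).

    Parameters
    ----------
    n_quad : Gauss-Hermite points per random-effect dimension (adaptive rule
        centred on the exact longitudinal posterior; 9 is conservative).
    model_death, model_dropout : include the auxiliary survival / attrition
        submodels that make trajectory-dependent censoring ignorable.
    max_iter, tol : EM iteration cap and absolute log-likelihood tolerance.
    """

    _param_names = ("n_quad", "max_iter", "tol", "model_death", "model_dropout",
                    "association", "analysis_waves")

    def __init__(self, n_quad: int = 9, max_iter: int = 40, tol: float = 0.1,
                 model_death: bool = True, model_dropout: bool = True,
                 association: str = "random-effects",
                 analysis_waves: tuple = ANALYSIS_WAVES):
        if association not in ("random-effects", "current-value"):
            raise ValueError("association must be 'random-effects' or 'current-value'")
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.tol = tol
        self.model_death = model_death
        self.model_dropout = model_dropout
        self.association = association
        self.analysis_waves = analysis_waves

    # ------------------------------------------------------------------ data
    def _build(self, panel: pd.DataFrame, statuses: pd.DataFrame,
               zscores: pd.DataFrame):
        waves = sorted(self.analysis_waves)
        st = statuses.set_index("person_id")
        prevalent = set(st.index[st["prevalent_at_entry"].astype(bool)])

        # person table: stable attributes of every non-prevalent participant
        obs = panel[panel["wave"].isin(waves)]
        first = obs.sort_values("wave").groupby("person_id").first()
        first = first[~first.index.isin(prevalent)]
        first["entry_age"] = first["age"] - (first["year"] - first["entry_year"])
        persons = first.reset_index()[
            ["person_id", "entry_year", "entry_age", "sex", "education",
             "midlife_obesity", "midlife_hypertension", "midlife_diabetes",
             "death_year"]
        ].copy()
        persons["female"] = (persons["sex"] == "f").astype(float)
        persons["educ_mid"] = (persons["education"] == "intermediate").astype(float)
        persons["educ_high"] = (persons["education"] == "higher").astype(float)
        persons["onset_year"] = persons["person_id"].map(st["onset_year"])
        pindex = pd.Series(np.arange(len(persons)), index=persons["person_id"])
        self._persons = persons

        # longitudinal rows: valid assessments strictly before ascertainment
        z = zscores[zscores["wave"].isin(waves)].merge(
            panel[["person_id", "wave", "entry_year", "midlife_obesity",
                   "midlife_hypertension", "midlife_diabetes"]],
            on=["person_id", "wave"])
        z = z[z["valid_assessment"] & z["mean_z"].notna()]
        z = z[~z["person_id"].isin(prevalent)]
        aw = pd.to_numeric(z["person_id"].map(st["ascertainment_year"]), errors="coerce")
        z = z[aw.isna() | (z["year"] < aw)]
        z = z[z["person_id"].isin(pindex.index)]
        z["entry_age"] = z["age"] - (z["year"] - z["entry_year"])
        z["time"] = (z["year"] - z["entry_year"]).astype(float)
        X = _long_design(z)
        y = z["mean_z"].to_numpy(dtype=float)
        ridx = pindex[z["person_id"]].to_numpy()
        trow = z["time"].to_numpy(dtype=float)
        self._long = dict(X=X, y=y, pidx=ridx, t=trow)

        n = len(persons)
        Zsum = np.column_stack([
            np.bincount(ridx, minlength=n),
            np.bincount(ridx, weights=trow, minlength=n),
            np.bincount(ridx, weights=trow**2, minlength=n),
        ])  # n_i, sum t, sum t^2
        self._ZtZ = np.zeros((n, 2, 2))
        self._ZtZ[:, 0, 0] = Zsum[:, 0]
        self._ZtZ[:, 0, 1] = self._ZtZ[:, 1, 0] = Zsum[:, 1]
        self._ZtZ[:, 1, 1] = Zsum[:, 2]
        self.n_long_obs_ = len(y)
        self.n_persons_ = n
        self._no_longitudinal = Zsum[:, 0] == 0
        self.persons_no_longitudinal_ = int(self._no_longitudinal.sum())

        # event blocks ---------------------------------------------------
        blocks = []
        ep = build_person_epochs(panel, statuses, tuple(waves))
        ep = ep[ep["person_id"].isin(pindex.index)]

        def block_from(df, name, d, Wcols):
            pid = pindex[df["person_id"]].to_numpy()
            pp = persons.iloc[pid]
            t_mid = (df["year_mid"].to_numpy() - pp["entry_year"].to_numpy()).astype(float)
            Xm, Xs = _long_design_at(
                pp["entry_age"].to_numpy(), t_mid, pp["female"].to_numpy(),
                df["year_mid"].to_numpy(dtype=float), pp["educ_mid"].to_numpy(),
                pp["educ_high"].to_numpy(), pp["midlife_obesity"].to_numpy(dtype=float),
                pp["midlife_hypertension"].to_numpy(dtype=float),
                pp["midlife_diabetes"].to_numpy(dtype=float))
            age_c = (df["age_mid"].to_numpy(dtype=float) - 75.0) / 10.0
            female = df["female"].to_numpy(dtype=float) if "female" in df else pp["female"].to_numpy()
            cols = {"const": np.ones(len(df)), "age_c": age_c, "age_c2": age_c**2,
                    "female": female,
                    "year_c": df["year_mid"].to_numpy(dtype=float) - BASE_YEAR,
                    "educ_mid": pp["educ_mid"].to_numpy(dtype=float),
                    "educ_high": pp["educ_high"].to_numpy(dtype=float),
                    "midlife_obesity": pp["midlife_obesity"].to_numpy(dtype=float),
                    "midlife_hypertension": pp["midlife_hypertension"].to_numpy(dtype=float),
                    "midlife_diabetes": pp["midlife_diabetes"].to_numpy(dtype=float)}
            for c in EVENT_RF:
                if c in df:
                    cols[c] = df[c].to_numpy(dtype=float)
            W = np.column_stack([cols[c] for c in Wcols])
            return _EventBlock(name=name, person=pid, d=np.asarray(d, dtype=float),
                               W=W, Xm=Xm, Xs=Xs, t=t_mid, colnames=list(Wcols))

        # under the random-effects association the deterministic trajectory
        # components must be absorbed by observed covariates, so the event
        # designs carry education and midlife risk factors explicitly
        extra = ([] if self.association == "current-value"
                 else ["educ_mid", "educ_high", "midlife_obesity",
                       "midlife_hypertension", "midlife_diabetes"])
        dem = ep[ep["outcome"] != "death"]
        blocks.append(block_from(
            dem, "dementia", (dem["outcome"] == "dementia").astype(float),
            ["const", "age_c", "age_c2", "female", "year_c"] + EVENT_RF + extra))
        self._dem_epochs = dem

        if self.model_death:
            dth = self._death_epochs(panel, persons, waves)
            blocks.append(block_from(dth, "death", dth["death"].to_numpy(),
                                     ["const", "age_c", "age_c2", "female", "year_c"]
                                     + extra))
        if self.model_dropout:
            dr = self._dropout_epochs(panel, persons, waves, st)
            blocks.append(block_from(dr, "dropout", dr["dropped"].to_numpy(),
                                     ["const"]))
        self._blocks = blocks

    def _death_epochs(self, panel, persons, waves):
        """All-cause death risk epochs: alive, entered, pre-onset (dropouts
        included -- vital status is linkage-observed)."""
        rows = []
        wave_years = sorted(panel.loc[panel["wave"].isin(waves), "year"].unique())
        for y0 in wave_years[:-1]:
            p = persons
            at = p[(p["entry_year"] <= y0)
                   & (p["death_year"].isna() | (p["death_year"] > y0))
                   & (p["onset_year"].isna() | (p["onset_year"] > y0 + 2))]
            df = at[["person_id", "entry_year"]].copy()
            df["year_mid"] = y0 + 1.0
            df["age_mid"] = at["entry_age"] + (y0 + 1.0 - at["entry_year"])
            df["female"] = at["female"]
            df["death"] = (at["death_year"].notna()
                           & (at["death_year"] > y0) & (at["death_year"] <= y0 + 2)).astype(float)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def _dropout_epochs(self, panel, persons, waves, st):
        """Attrition risk epochs: interviewed at wave e, survived the epoch."""
        obs = panel[panel["wave"].isin(waves)]
        key = set(zip(obs["person_id"], obs["wave"]))
        e = obs[obs["wave"] < max(waves)].merge(
            persons[["person_id"]], on="person_id")
        alive_through = e["death_year"].isna() | (e["death_year"] > e["year"] + 2)
        e = e[alive_through].copy()
        e["dropped"] = [
            0.0 if (p, w + 1) in key else 1.0
            for p, w in zip(e["person_id"], e["wave"])
        ]
        e["year_mid"] = e["year"] + 1.0
        e["age_mid"] = e["age"] + 1.0
        return e[["person_id", "wave", "year_mid", "age_mid", "dropped"]].merge(
            persons[["person_id", "entry_year", "female"]], on="person_id")

    # ------------------------------------------------------------- internals
    def _posteriors(self, beta, sigma2, Sigma):
        """Exact longitudinal posterior N(bhat, V) per person, plus the LMM
        log-likelihood (closed form)."""
        Xl, yl, pidx = self._long["X"], self._long["y"], self._long["pidx"]
        t = self._long["t"]
        n = self.n_persons_
        r = yl - Xl @ beta
        Zr = np.column_stack([np.bincount(pidx, weights=r, minlength=n),
                              np.bincount(pidx, weights=r * t, minlength=n)])
        SSR = np.bincount(pidx, weights=r**2, minlength=n)
        Sinv, detS = _inv2(Sigma[None, :, :])
        P = Sinv + self._ZtZ / sigma2
        V, detP = _inv2(P)
        bhat = np.einsum("nij,nj->ni", V, Zr) / sigma2
        ni = self._ZtZ[:, 0, 0]
        detV = 1.0 / detP
        quad = (SSR - np.einsum("ni,nij,nj->n", Zr, V, Zr) / sigma2) / sigma2
        ll = -0.5 * (ni * np.log(2 * np.pi * sigma2)
                     + np.log(detS[0] / detV) + quad)
        return bhat, V, ll

    def _node_pass(self, beta, blocks_eta, bhat, Lc, nodes, logw, collect):
        """Iterate nodes accumulating per-person event log-likelihood, and
        (optionally) posterior-weighted Newton statistics.

        blocks_eta: per block (eta_hat, u, v) row vectors; collect: None for
        the E-pass, else the tilted weights omega (n, K) for the M-pass.
        """
        n = self.n_persons_
        K = nodes.shape[0]
        if collect is None:
            M = np.zeros((n, K))
            for k in range(K):
                z1, z2 = nodes[k]
                for blk, (eta0, u, v) in zip(self._blocks, blocks_eta):
                    eta = eta0 + u * z1 + v * z2
                    ll = np.where(blk.d > 0, log_expit(eta), log_expit(-eta))
                    M[:, k] += np.bincount(blk.person, weights=ll, minlength=n)
            return M
        omega = collect
        stats = []
        for blk in self._blocks:
            k_w = blk.k
            stats.append(dict(
                g=np.zeros(len(blk.d)), h=np.zeros(len(blk.d)),
                gm=np.zeros(len(blk.d)), gs=np.zeros(len(blk.d)),
                hm=np.zeros(len(blk.d)), hs=np.zeros(len(blk.d)),
                hm2=np.zeros(len(blk.d)), hs2=np.zeros(len(blk.d)),
                hms=np.zeros(len(blk.d))))
        for k in range(K):
            z1, z2 = nodes[k]
            b0 = bhat[:, 0] + Lc[:, 0, 0] * z1
            b1 = bhat[:, 1] + Lc[:, 1, 0] * z1 + Lc[:, 1, 1] * z2
            for blk, (eta0, u, v), s in zip(self._blocks, blocks_eta, stats):
                w = omega[blk.person, k]
                eta = eta0 + u * z1 + v * z2
                p = expit(eta)
                resid = w * (blk.d - p)
                fish = w * p * (1.0 - p)
                m_n = blk._mfix + b0[blk.person] + b1[blk.person] * blk.t
                s_n = blk._sfix + b1[blk.person]
                s["g"] += resid
                s["h"] += fish
                s["gm"] += resid * m_n
                s["gs"] += resid * s_n
                s["hm"] += fish * m_n
                s["hs"] += fish * s_n
                s["hm2"] += fish * m_n**2
                s["hs2"] += fish * s_n**2
                s["hms"] += fish * m_n * s_n
        return stats

    def _etas(self, beta, bhat, Lc):
        """Per-block (eta_hat, u, v): linear predictor at the posterior mean
        and its loadings on the standardised node coordinates."""
        out = []
        current_value = self.association == "current-value"
        for blk, gamma in zip(self._blocks, self._gammas):
            g, av, as_ = gamma[:-2], gamma[-2], gamma[-1]
            blk._mfix = blk.Xm @ beta if current_value else np.zeros(len(blk.d))
            blk._sfix = blk.Xs @ beta if current_value else np.zeros(len(blk.d))
            A = np.full(len(blk.d), av)
            C = av * blk.t + as_
            pid = blk.person
            eta0 = (blk.W @ g
                    + av * (blk._mfix + bhat[pid, 0] + bhat[pid, 1] * blk.t)
                    + as_ * (blk._sfix + bhat[pid, 1]))
            u = A * Lc[pid, 0, 0] + C * Lc[pid, 1, 0]
            v = C * Lc[pid, 1, 1]
            out.append((eta0, u, v))
        return out

    # ------------------------------------------------------------------ fit
    def fit(self, panel: pd.DataFrame, statuses: pd.DataFrame,
            zscores: pd.DataFrame | None = None):
        if zscores is None:
            from .ascertain import standardize_domain_scores
            zscores = standardize_domain_scores(panel)
        self._build(panel, statuses, zscores)
        Xl, yl = self._long["X"], self._long["y"]
        p = Xl.shape[1]

        # ---- two-stage initialisation (longitudinal-only EM) -------------
        XtX = Xl.T @ Xl
        pidx, t = self._long["pidx"], self._long["t"]
        beta, sigma2, Sigma, _ = fit_linear_mixed(Xl, yl, pidx, t, n_iter=40)
        bhat, V, _ = self._posteriors(beta, sigma2, Sigma)

        # event-coefficient initialisation: plug-in empirical-Bayes fits
        self._gammas = []
        cv = self.association == "current-value"
        for blk in self._blocks:
            m_hat = (blk.Xm @ beta if cv else 0.0) + bhat[blk.person, 0] + bhat[blk.person, 1] * blk.t
            s_hat = (blk.Xs @ beta if cv else 0.0) + bhat[blk.person, 1]
            U = np.column_stack([blk.W, m_hat, s_hat])
            g = np.zeros(U.shape[1])
            g[0] = np.log(max(blk.d.mean(), 1e-4) / (1 - min(blk.d.mean(), 0.9999)))
            for _ in range(8):
                eta = U @ g
                mu = expit(eta)
                grad = U.T @ (blk.d - mu)
                H = (U * (mu * (1 - mu))[:, None]).T @ U + 1e-8 * np.eye(U.shape[1])
                step = np.linalg.solve(H, grad)
                g = g + np.clip(step, -2, 2)
            self._gammas.append(g)

        # ---- full EM ------------------------------------------------------
        nodes, logw = _gh_nodes(self.n_quad)
        loglik_path = []
        self.converged_ = False
        for it in range(self.max_iter):
            bhat, V, ll_lmm = self._posteriors(beta, sigma2, Sigma)
            Lc = _chol2(V)
            etas = self._etas(beta, bhat, Lc)
            M = self._node_pass(beta, etas, bhat, Lc, nodes, logw, None)
            Mw = M + logw[None, :]
            ll_ev = logsumexp(Mw, axis=1)
            loglik = float(ll_lmm.sum() + ll_ev.sum())
            loglik_path.append(loglik)
            omega = np.exp(Mw - ll_ev[:, None])

            # posterior moments of b
            mz1 = omega @ nodes[:, 0]
            mz2 = omega @ nodes[:, 1]
            mz11 = omega @ (nodes[:, 0] ** 2)
            mz22 = omega @ (nodes[:, 1] ** 2)
            mz12 = omega @ (nodes[:, 0] * nodes[:, 1])
            Lmz = np.column_stack([Lc[:, 0, 0] * mz1,
                                   Lc[:, 1, 0] * mz1 + Lc[:, 1, 1] * mz2])
            Eb = bhat + Lmz
            Ezz = np.empty((self.n_persons_, 2, 2))
            Ezz[:, 0, 0] = mz11
            Ezz[:, 0, 1] = Ezz[:, 1, 0] = mz12
            Ezz[:, 1, 1] = mz22
            LEz = np.einsum("nij,njk->nik", Lc, Ezz)
            LEzL = np.einsum("nij,nkj->nik", LEz, Lc)
            Ebb = (np.einsum("ni,nj->nij", bhat, bhat)
                   + np.einsum("ni,nj->nij", bhat, Lmz)
                   + np.einsum("ni,nj->nij", Lmz, bhat) + LEzL)

            # M-step: variance components
            Sigma_new = Ebb.mean(axis=0)
            # M-step: Newton stats for event coefficients and beta
            stats = self._node_pass(beta, etas, bhat, Lc, nodes, logw, omega)

            # beta update (longitudinal quadratic + event coupling)
            pred_b = Eb[pidx, 0] + Eb[pidx, 1] * t
            grad_b = Xl.T @ (yl - Xl @ beta - pred_b) / sigma2
            H_b = XtX / sigma2
            if self.association == "current-value":
                for blk, gamma, s in zip(self._blocks, self._gammas, stats):
                    av, as_ = gamma[-2], gamma[-1]
                    D = av * blk.Xm + as_ * blk.Xs
                    grad_b += D.T @ s["g"]
                    H_b += (D * s["h"][:, None]).T @ D
            beta_new = beta + np.linalg.solve(H_b + 1e-10 * np.eye(p), grad_b)

            # sigma^2 update: E[(y - Xb - Zb)^2] = r^2 + tr(ZtZ Cov[b])
            r = yl - Xl @ beta_new - pred_b
            covb = Ebb - np.einsum("ni,nj->nij", Eb, Eb)
            tr_corr = np.einsum("nij,nij->n", self._ZtZ, covb)
            sigma2_new = float((r @ r + tr_corr.sum()) / len(yl))

            # event-coefficient updates (one damped Newton step per block)
            new_gammas = []
            for blk, gamma, s in zip(self._blocks, self._gammas, stats):
                kk = blk.k
                grad = np.concatenate([blk.W.T @ s["g"], [s["gm"].sum()], [s["gs"].sum()]])
                H = np.empty((kk + 2, kk + 2))
                H[:kk, :kk] = (blk.W * s["h"][:, None]).T @ blk.W
                H[:kk, kk] = H[kk, :kk] = blk.W.T @ s["hm"]
                H[:kk, kk + 1] = H[kk + 1, :kk] = blk.W.T @ s["hs"]
                H[kk, kk] = s["hm2"].sum()
                H[kk + 1, kk + 1] = s["hs2"].sum()
                H[kk, kk + 1] = H[kk + 1, kk] = s["hms"].sum()
                step = np.linalg.solve(H + 1e-8 * np.eye(kk + 2), grad)
                new_gammas.append(gamma + np.clip(step, -1.0, 1.0))
                if blk.name == "dementia":
                    self._dem_hessian = H

            delta = abs(loglik_path[-1] - loglik_path[-2]) if it else np.inf
            beta, sigma2, Sigma = beta_new, sigma2_new, 0.5 * (Sigma_new + Sigma_new.T)
            self._gammas = new_gammas
            if delta < self.tol and it >= 3:
                self.converged_ = True
                break

        self.n_iter_ = len(loglik_path)
        self.loglik_path_ = loglik_path
        self.loglik_ = loglik_path[-1]
        if not self.converged_:
            warnings.warn("joint model EM did not reach the log-likelihood "
                          "tolerance; result flagged non-converged")

        self.beta_ = pd.Series(beta, index=LONG_COLUMNS)
        self.sigma_ = float(np.sqrt(sigma2))
        self.re_cov_ = Sigma
        self.coefs_ = {}
        self.alpha_ = {}
        for blk, gamma in zip(self._blocks, self._gammas):
            self.coefs_[blk.name] = pd.Series(gamma, index=blk.colnames + ["alpha_value", "alpha_slope"])
            self.alpha_[blk.name] = (gamma[-2], gamma[-1])

        # approximate covariance of the dementia submodel from the final
        # expected-information matrix (documented approximation)
        names = self.coefs_["dementia"].index
        cov = np.linalg.inv(self._dem_hessian + 1e-8 * np.eye(len(names)))
        self.dem_cov_ = pd.DataFrame(cov, index=names, columns=names)
        se = np.sqrt(np.diag(cov))
        i_year = list(names).index("year_c")
        self.trend_ = trend_from_coef(self.coefs_["dementia"]["year_c"], se[i_year],
                                      "joint")

        # persist posterior pieces for prediction
        bhat, V, _ = self._posteriors(beta, sigma2, Sigma)
        Lc = _chol2(V)
        etas = self._etas(beta, bhat, Lc)
        M = self._node_pass(beta, etas, bhat, Lc, nodes, logw, None)
        Mw = M + logw[None, :]
        self._post = dict(bhat=bhat, Lc=Lc,
                          omega=np.exp(Mw - logsumexp(Mw, axis=1)[:, None]),
                          nodes=nodes)
        return self

    # -------------------------------------------------------------- predict
    def predict_dementia_probability(self, panel: pd.DataFrame,
                                     statuses: pd.DataFrame) -> pd.DataFrame:
        """Per-person, per-epoch incident-dementia probabilities.

        Rows cover every non-prevalent participant alive and dementia-free at
        the epoch start -- including epochs after dropout (the correction the
        joint model exists for).  Time-varying risk factors are carried
        forward from the last interview.  Probabilities condition on being
        event-free at the epoch start via the person's own posterior.
        """
        if not hasattr(self, "_post"):
            raise RuntimeError("model is not fitted")
        persons = self._persons
        waves = sorted(self.analysis_waves)
        wave_years = sorted(panel.loc[panel["wave"].isin(waves), "year"].unique())

        obs = panel[panel["wave"].isin(waves)][["person_id", "year"] + EVENT_RF]
        rows = []
        for y0 in wave_years[:-1]:
            at = persons[(persons["entry_year"] <= y0)
                         & (persons["death_year"].isna() | (persons["death_year"] > y0))
                         & (persons["onset_year"].isna() | (persons["onset_year"] > y0))]
            df = at[["person_id", "entry_year", "entry_age", "female", "educ_mid",
                     "educ_high", "midlife_obesity", "midlife_hypertension",
                     "midlife_diabetes", "onset_year"]].copy()
            df["year_mid"] = y0 + 1.0
            df["year0"] = float(y0)
            rows.append(df)
        pred = pd.concat(rows, ignore_index=True)
        # carry risk factors forward from the most recent interview
        rf = obs.sort_values("year").rename(columns={"year": "rf_year"})
        rf["rf_year"] = rf["rf_year"].astype(float)
        pred = pd.merge_asof(
            pred.sort_values("year0"), rf,
            left_on="year0", right_on="rf_year", by="person_id", direction="backward")
        for c in EVENT_RF:
            pred[c] = pred[c].fillna(0.0)
        pred["under_observation"] = pred["rf_year"] == pred["year0"]
        pred["age_mid"] = pred["entry_age"] + (pred["year_mid"] - pred["entry_year"])
        pred["time_mid"] = pred["year_mid"] - pred["entry_year"]
        pred = pred.sort_values(["person_id", "year_mid"]).reset_index(drop=True)

        gamma = self.coefs_["dementia"].to_numpy()
        g, av, as_ = gamma[:-2], gamma[-2], gamma[-1]
        Xm, Xs = _long_design_at(
            pred["entry_age"].to_numpy(), pred["time_mid"].to_numpy(),
            pred["female"].to_numpy(), pred["year_mid"].to_numpy(),
            pred["educ_mid"].to_numpy(), pred["educ_high"].to_numpy(),
            pred["midlife_obesity"].to_numpy(dtype=float),
            pred["midlife_hypertension"].to_numpy(dtype=float),
            pred["midlife_diabetes"].to_numpy(dtype=float))
        age_c = (pred["age_mid"].to_numpy() - 75.0) / 10.0
        Wcols = {"const": np.ones(len(pred)), "age_c": age_c, "age_c2": age_c**2,
                 "female": pred["female"].to_numpy(dtype=float),
                 "year_c": pred["year_mid"].to_numpy() - BASE_YEAR}
        for c in EVENT_RF + ["educ_mid", "educ_high", "midlife_obesity",
                             "midlife_hypertension", "midlife_diabetes"]:
            Wcols[c] = pred[c].to_numpy(dtype=float)
        W = np.column_stack([Wcols[c] for c in self.coefs_["dementia"].index[:-2]])

        beta = self.beta_.to_numpy()
        if self.association == "current-value":
            base = W @ g + av * (Xm @ beta) + as_ * (Xs @ beta)
        else:
            base = W @ g
        t_mid = pred["time_mid"].to_numpy()

        pindex = pd.Series(np.arange(len(persons)), index=persons["person_id"])
        pid = pindex[pred["person_id"]].to_numpy()
        pred["prior_random_effects"] = self._no_longitudinal[pid]

        bhat, Lc = self._post["bhat"], self._post["Lc"]
        omega, nodes = self._post["omega"], self._post["nodes"]
        K = nodes.shape[0]
        n_rows = len(pred)

        # within-person prefix products of survival (rows sorted person, epoch)
        ids = pred["person_id"].to_numpy()
        new_person = np.r_[True, ids[1:] != ids[:-1]]
        start = np.maximum.accumulate(np.where(new_person, np.arange(n_rows), 0))
        num = np.zeros(n_rows)
        den = np.zeros(n_rows)
        for k in range(K):
            z1, z2 = nodes[k]
            b0 = bhat[pid, 0] + Lc[pid, 0, 0] * z1
            b1 = bhat[pid, 1] + Lc[pid, 1, 0] * z1 + Lc[pid, 1, 1] * z2
            eta = base + av * (b0 + b1 * t_mid) + as_ * b1
            pk = expit(eta)
            excl = np.cumsum(np.log1p(-pk)) - np.log1p(-pk)  # exclusive prefix
            Sprev = np.exp(excl - excl[start])
            wk = omega[pid, k]
            num += wk * pk * Sprev
            den += wk * Sprev
        pred["p_dementia"] = np.clip(num / den, 1e-12, 1 - 1e-12)
        keep = ["person_id", "year0", "year_mid", "age_mid", "female",
                "under_observation", "prior_random_effects", "p_dementia"] + EVENT_RF
        return pred[keep]
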