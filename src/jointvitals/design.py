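"""Per-subject design assembly shared by the mixed and joint models.

Fixed-effect formulas are given per outcome as a list of expanded
(one-hot) baseline design columns; every outcome model implicitly starts
with an intercept and the visit index t/6.  The packed fixed-effect vector
concatenates the per-outcome coefficient blocks in canonical outcome order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OUTCOMES, CohortDataset
from .params import INTERCEPT, K, VISIT, MLMMParams, visit_index

Formulas = dict[str, list[str]]


def formulas_from_params(params: MLMMParams) -> Formulas:
    return {
        k: [c for c in params.beta[k].index if c not in (INTERCEPT, VISIT)]
        for k in params.outcomes
    }


@dataclass
class PreparedSubject:
    subject_id: str
    y: np.ndarray          # stacked measurements, outcomes in canonical order
    k_row: np.ndarray      # outcome index per measurement row
    visit: np.ndarray      # visit index per measurement row
    X: np.ndarray          # (n_i, p_beta) block design for the packed beta
    Z: np.ndarray          # (n_i, 2K) random-effect design
    T: float               # observed time (hours)
    delta: int             # event indicator
    xs: np.ndarray         # survival design row
    x0: dict[str, np.ndarray]  # per-outcome fixed design at visit 0 (visit col zeroed)


@dataclass
class Prepared:
    subjects: list[PreparedSubject]
    formulas: Formulas
    beta_names: list[tuple[str, str]]   # (outcome, coefficient) in packed order
    beta_slices: dict[str, slice]
    p_beta: int
    surv_names: list[str]

    @property
    def n(self) -> int:
        return len(self.subjects)

    def pack_beta(self, beta: dict[str, pd.Series]) -> np.ndarray:
        out = np.empty(self.p_beta)
        for k, sl in self.beta_slices.items():
            names = [INTERCEPT, VISIT] + self.formulas[k]
            out[sl] = beta[k].reindex(names).to_numpy()
        return out

    def unpack_beta(self, vec: np.ndarray) -> dict[str, pd.Series]:
        out = {}
        for k, sl in self.beta_slices.items():
            names = [INTERCEPT, VISIT] + self.formulas[k]
            out[k] = pd.Series(np.asarray(vec[sl], dtype=float), index=names)
        return out


def prepare(
    dataset: CohortDataset,
    formulas: Formulas | None = None,
    survival_covariates: list[str] | None = None,
) -> Prepared:
    """Assemble per-subject arrays for likelihood evaluation.

    ``formulas`` maps outcome codes to lists of expanded design columns
    (default: intercept + visit only for each outcome present).
    """
    present = [k for k in OUTCOMES if k in set(dataset.longitudinal["outcome"])]
    if formulas is None:
        formulas = {k: [] for k in present}
    formulas = {k: list(v) for k, v in formulas.items() if k in OUTCOMES}
    outcomes = [k for k in OUTCOMES if k in formulas]

    design = dataset.covariate_design()
    surv_names = list(survival_covariates or [])
    for c in surv_names:
        if c not in design.columns:
            raise KeyError(f"survival covariate {c!r} not in expanded design")

    slices: dict[str, slice] = {}
    names: list[tuple[str, str]] = []
    start = 0
    for k in outcomes:
        cols = [INTERCEPT, VISIT] + formulas[k]
        slices[k] = slice(start, start + len(cols))
        names.extend((k, c) for c in cols)
        start += len(cols)
    p_beta = start

    long = dataset.longitudinal
    surv = dataset.survival
    by_subject = {
        sid: g for sid, g in long.groupby("subject_id", sort=False)
    }
    subjects = []
    for row_idx, srow in surv.iterrows():
        sid = srow["subject_id"]
        g = by_subject.get(sid)
        drow = design.loc[row_idx]
        ys, ks, vs, Xs, Zs = [], [], [], [], []
        x0 = {}
        for k_idx, k in enumerate(OUTCOMES):
            if k not in formulas:
                continue
            cols = formulas[k]
            xcov = drow[cols].to_numpy(dtype=float) if cols else np.empty(0)
            x0[k] = np.concatenate(([1.0, 0.0], xcov))
            if g is None:
                continue
            gk = g[g["outcome"] == k].sort_values("time_h")
            if not len(gk):
                continue
            v = visit_index(gk["time_h"].to_numpy())
            m = len(v)
            Xi = np.zeros((m, p_beta))
            Xi[:, slices[k]] = np.column_stack(
                [np.ones(m), v]
                + [np.repeat(xcov[j], m) for j in range(len(cols))]
            )
            Zi = np.zeros((m, 2 * K))
            Zi[:, 2 * k_idx] = 1.0
            Zi[:, 2 * k_idx + 1] = v
            ys.append(gk["value"].to_numpy(dtype=float))
            ks.append(np.full(m, k_idx))
            vs.append(v)
            Xs.append(Xi)
            Zs.append(Zi)
        subjects.append(
            PreparedSubject(
                subject_id=sid,
                y=np.concatenate(ys) if ys else np.empty(0),
                k_row=np.concatenate(ks).astype(int) if ks else np.empty(0, int),
                visit=np.concatenate(vs) if vs else np.empty(0),
                X=np.vstack(Xs) if Xs else np.empty((0, p_beta)),
                Z=np.vstack(Zs) if Zs else np.empty((0, 2 * K)),
                T=float(srow["observed_time_h"]),
                delta=int(srow["event"]),
                xs=drow[surv_names].to_numpy(dtype=float)
                if surv_names
                else np.empty(0),
                x0=x0,
            )
        )
    return Prepared(subjects, formulas, names, slices, p_beta, surv_names)
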