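"""Otolith element-chemistry QC, size detrending and discrimination.

Otolith trace-element concentrations record the water a fish grew in,
so they act as a natural tag of natal region.  Before discrimination,
elements must pass detection-limit and instrument-precision QC, and
concentrations that scale with otolith radius (fish size) are detrended
with a common ANCOVA slope so that size structure does not masquerade
as regional signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

DEFAULT_LOD_FRACTION = 0.90
DEFAULT_CV_LIMIT = 10.5          # percent


class DetrendError(ValueError):
    pass


def qc_filter(table: pd.DataFrame, elements, standard_cv: dict,
              groups=("NS", "SS"), lod_fraction: float = DEFAULT_LOD_FRACTION,
              cv_limit: float = DEFAULT_CV_LIMIT) -> list:
    """Retain elements measurable enough to use as tags.

    An element passes iff at least ``lod_fraction`` of samples are above
    the detection limit within *each* breeding area separately, and the
    glass-standard coefficient of variation is below ``cv_limit``
    percent.  Decisions are per-element and order-independent.
    """
    retained = []
    for el in elements:
        cv = standard_cv.get(el)
        if cv is None or not cv < cv_limit:
            continue
        flag_col = f"{el}_above_lod"
        ok = True
        for g in groups:
            sub = table[table["group"] == g]
            if len(sub) == 0 or sub[flag_col].mean() < lod_fraction:
                ok = False
                break
        if ok:
            retained.append(el)
    return retained


@dataclass
class DetrendModel:
    """Common-slope ANCOVA fit of concentration on otolith radius.

    ``usable`` is False when the group × radius interaction is
    significant (slopes differ by region, so a common detrend is
    invalid and the element cannot be used for discrimination).
    """

    element: str
    interaction_p: float
    slope: float
    slope_p: float
    reference_radius: float
    usable: bool
    significant: bool


def fit_detrend(table: pd.DataFrame, element: str,
                alpha: float = 0.05) -> DetrendModel:
    """ANCOVA screen concentration ~ group + radius (+ interaction).

    The interaction model is fitted first; a significant interaction
    marks the element unusable.  Otherwise the additive model's common
    radius slope is returned, flagged significant when its p < alpha.
    """
    counts = table.groupby("group").size()
    if (counts < 3).any() or len(counts) < 2:
        raise DetrendError("need >= 3 fish in each of >= 2 groups")
    df = table[["group", "radius_um", element]].rename(
        columns={element: "conc", "radius_um": "radius"}).dropna()
    try:
        full = smf.ols("conc ~ C(group) * radius", data=df).fit()
        add = smf.ols("conc ~ C(group) + radius", data=df).fit()
    except Exception as exc:       # singular design
        raise DetrendError(f"degenerate design for {element}: {exc}")
    inter_terms = [t for t in full.pvalues.index if ":" in t]
    interaction_p = float(min(full.pvalues[t] for t in inter_terms))
    if interaction_p < alpha:
        return DetrendModel(element, interaction_p, float("nan"),
                            float("nan"), float(df["radius"].mean()),
                            usable=False, significant=False)
    slope = float(add.params["radius"])
    slope_p = float(add.pvalues["radius"])
    return DetrendModel(element, interaction_p, slope, slope_p,
                        reference_radius=float(df["radius"].mean()),
                        usable=True, significant=slope_p < alpha)


def apply_detrend(table: pd.DataFrame, model: DetrendModel) -> pd.DataFrame:
    """Remove the common size trend from one element's concentrations.

    adjusted = observed − slope · (radius − reference mean radius);
    centring at the reference radius preserves group means there.
    """
    if not model.usable:
        raise DetrendError(
            f"{model.element}: interaction significant, detrend refused")
    out = table.copy()
    out[model.element] = (
        table[model.element]
        - model.slope * (table["radius_um"] - model.reference_radius))
    return out


def _make_classifier(method: str, priors):
    if method.upper() == "LDA":
        return LinearDiscriminantAnalysis(priors=priors)
    if method.upper() == "QDA":
        return QuadraticDiscriminantAnalysis(priors=priors)
    raise ValueError("method must be 'LDA' or 'QDA'")


def discriminant_self_assign(table: pd.DataFrame, elements,
                             method: str = "LDA", priors=None):
    """Jackknifed (leave-one-out) discriminant self-assignment.

    Each fish is classified by a discriminant function refitted without
    it (equal class priors by default).  Returns ``(calls_df,
    accuracy)`` with percent correct per group and overall.
    """
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if (table.groupby("group").size() < 3).any():
        raise ValueError("need >= 3 fish per group")
    X = table[list(elements)].to_numpy(dtype=float)
    y = table["group"].to_numpy()
    if priors is None:
        priors = np.full(len(groups), 1.0 / len(groups))
    n = len(table)
    calls = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = _make_classifier(method, priors)
        try:
            clf.fit(X[mask], y[mask])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular covariance over features {list(elements)}: {exc}")
        post = clf.predict_proba(X[i:i + 1])[0]
        call = clf.classes_[int(np.argmax(post))]
        calls.append({"id": table["id"].iloc[i], "group": y[i],
                      "call": call,
                      **{f"post_{c}": p for c, p in
                         zip(clf.classes_, post)},
                      "correct": call == y[i]})
    calls_df = pd.DataFrame(calls)
    accuracy = {g: 100.0 * calls_df[calls_df["group"] == g]["correct"].mean()
                for g in groups}
    accuracy["overall"] = 100.0 * calls_df["correct"].mean()
    return calls_df, accuracy


def classify_juveniles_otolith(larvae: pd.DataFrame,
                               juveniles: pd.DataFrame, elements,
                               method: str = "LDA",
                               assign_at: float = 0.70, priors=None):
    """Classify unknown-origin juveniles with a larva-trained model.

    A juvenile is assigned to the region whose posterior reaches
    ``assign_at`` (default 70%); below that the assignment fails.
    Juveniles missing any model feature are dropped with a notice in
    the summary.  Returns ``(calls_df, summary)`` with the summary in
    percent of analysed juveniles.
    """
    groups = sorted(larvae["group"].unique())
    if priors is None:
        priors = np.full(len(groups), 1.0 / len(groups))
    clf = _make_classifier(method, priors)
    clf.fit(larvae[list(elements)].to_numpy(dtype=float),
            larvae["group"].to_numpy())
    usable = juveniles.dropna(subset=list(elements))
    n_dropped = len(juveniles) - len(usable)
    rows = []
    for _, fish in usable.iterrows():
        post = clf.predict_proba(
            fish[list(elements)].to_numpy(dtype=float)[None, :])[0]
        k = int(np.argmax(post))
        if post[k] >= assign_at:
            status, call = "assigned", clf.classes_[k]
        else:
            status, call = "failed", None
        rows.append({"id": fish["id"], "status": status, "call": call,
                     **{f"post_{c}": p for c, p in
                        zip(clf.classes_, post)}})
    calls_df = pd.DataFrame(rows)
    n = len(calls_df)
    summary = {"n": n, "n_dropped_missing_features": n_dropped}
    for g in groups:
        summary[f"pct_{g}"] = (100.0 * (calls_df["call"] == g).sum() / n
                               if n else 0.0)
    summary["pct_failed"] = (100.0 * (calls_df["status"] == "failed").sum()
                             / n if n else 0.0)
    return calls_df, summary
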