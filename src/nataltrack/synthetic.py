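"""Synthetic inputs with known ground truth for recovery testing.

Generates the three data streams the pipeline consumes — capture
records of passively drifting larvae (forward-integrated through a flow
field so a controllable fraction crosses the region boundary before
"capture"), two-subpopulation microsatellite genotypes at a target
divergence (Balding–Nichols model), and region-specific otolith
chemistry with a size trend — together with a :class:`ScenarioTruth`
recording every true hatch region, date and mixture proportion.

The natural-tag premise is built in: genotypes and otolith chemistry
are always drawn from an individual's *true* hatch region, never its
capture region, so mislabelled training data degrades discrimination
exactly as pre-capture drift would in the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nataltrack.flowfield import FlowField, RegionPartition
from nataltrack.backtrack import (
    CaptureRecord,
    CoverageError,
    ParticleCloud,
    TransportConfig,
    _advect_step,
    SECONDS_PER_DAY,
)
from nataltrack.popgen import GenotypeTable

# otolith element distributions by hatch region, µg/g (mean, SD)
DEFAULT_ELEMENT_PARAMS = {
    "Sr": {"SS": (847.0, 216.0), "NS": (443.0, 55.0)},
    "Ba": {"SS": (30.0, 24.0), "NS": (99.0, 37.0)},
}
# common concentration-vs-radius slopes (µg/g per µm)
DEFAULT_TREND_SLOPES = {"Sr": -0.00134, "Ba": -0.340}


@dataclass
class ScenarioTruth:
    """Ground truth of one synthetic cohort."""

    individuals: pd.DataFrame    # id, role, true_region, age_days, ...
    params: dict

    @property
    def mixture(self) -> dict:
        juv = self.individuals[self.individuals["role"] == "juvenile"]
        if len(juv) == 0:
            return {}
        frac = juv["true_region"].value_counts(normalize=True)
        return frac.to_dict()


def _tl_from_age(age_days, rng):
    """Monotone larval growth: ~5 mm at hatch, ~0.6 mm/day."""
    tl = 5.0 + 0.6 * np.asarray(age_days, dtype=float) \
        + rng.normal(0.0, 0.5, size=np.shape(age_days))
    return np.maximum(tl, 5.0)


def gen_larvae(field: FlowField, n: int = 100,
               partition: RegionPartition | None = None,
               advect_fraction: float = 0.3,
               north_fraction: float = 0.5,
               age_range=(3, 12), seed: int = 0,
               config: TransportConfig | None = None,
               jet_centre_x: float | None = None,
               jet_width: float = 6_000.0):
    """Forward-simulate a larval cohort with known hatch regions.

    ``advect_fraction`` of the cohort hatches in the north region inside
    the plume jet, close enough to the boundary that the southward
    current carries it across before capture; the rest hatch in still
    water well away from the boundary (north or south per
    ``north_fraction`` of the non-advected remainder).  Every larva is
    integrated forward with the full stochastic transport scheme from
    its hatch time to the common capture time, so realised crossings
    (not just intent) are recorded in the truth table.
    """
    partition = partition or RegionPartition()
    config = config or TransportConfig(dt=1800.0, seed=seed)
    rng = np.random.default_rng(seed)
    x_lo, x_hi = field.x_axis[0], field.x_axis[-1]
    boundary_y = (partition.boundary_latitude - field.origin_lat) * 111_320.0
    if not field.y_axis[0] < boundary_y < field.y_axis[-1]:
        raise ValueError("partition boundary outside the grid span")
    if jet_centre_x is None:
        jet_centre_x = 0.5 * (x_lo + x_hi)

    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    t_capture = field.times[-1]
    max_span_s = (t_capture - field.times[0]) / np.timedelta64(1, "s")
    if ages.max() * SECONDS_PER_DAY > max_span_s:
        raise CoverageError(
            f"field span {max_span_s / 86400:.1f} d shorter than the "
            f"maximum age {ages.max()} d")

    n_adv = int(round(advect_fraction * n))
    n_still = n - n_adv
    n_north_still = int(round(north_fraction * n_still))
    kinds = np.array(["jet"] * n_adv + ["north"] * n_north_still
                     + ["south"] * (n_still - n_north_still))
    rng.shuffle(kinds)

    x0 = np.empty(n)
    y0 = np.empty(n)
    jitter = lambda m, s: rng.uniform(-s, s, m)
    jet = kinds == "jet"
    north = kinds == "north"
    south = kinds == "south"
    x0[jet] = jet_centre_x + jitter(jet.sum(), 0.3 * jet_width)
    y0[jet] = boundary_y + 1_500.0 + jitter(jet.sum(), 500.0)
    far = 2.5 * jet_width
    side = np.where(rng.random(north.sum()) < 0.5, -1.0, 1.0)
    x0[north] = np.clip(jet_centre_x + side * far
                        + jitter(north.sum(), 2_000.0),
                        x_lo + 500, x_hi - 500)
    y0[north] = np.minimum(field.y_axis[-1] - 1_000.0,
                           boundary_y + 10_000.0 + jitter(north.sum(),
                                                          3_000.0))
    # south-hatched larvae sit outside the jet so they stay south
    side_s = np.where(rng.random(south.sum()) < 0.5, -1.0, 1.0)
    x0[south] = np.clip(jet_centre_x + side_s * far
                        + jitter(south.sum(), 2_000.0),
                        x_lo + 500, x_hi - 500)
    y0[south] = np.maximum(field.y_axis[0] + 1_000.0,
                           boundary_y - 9_000.0 + jitter(south.sum(),
                                                         3_000.0))
    x0 = np.clip(x0, x_lo, x_hi)
    y0 = np.clip(y0, y_lo := field.y_axis[0], field.y_axis[-1])
    true_lat = field.origin_lat + y0 / 111_320.0
    true_region = np.asarray(partition.label_of_latitude(true_lat))

    hatch_times = t_capture - ages.astype("timedelta64[D]").astype(
        "timedelta64[s]") * 1
    # global clock: advance only already-hatched larvae each step
    cloud = ParticleCloud(x=x0.copy(), y=y0.copy(),
                          z=np.full(n, 1.0),
                          active=np.zeros(n, dtype=bool),
                          rng=np.random.default_rng(
                              rng.integers(2**31)))
    t = t_capture - np.timedelta64(int(ages.max()) * SECONDS_PER_DAY, "s")
    dt = np.timedelta64(int(config.dt), "s")
    while t < t_capture:
        cloud.active = hatch_times <= t
        _advect_step(cloud, field, t, config, direction=+1)
        t = t + dt

    lon, lat = field.xy_to_lonlat(cloud.x, cloud.y)
    capture_region = np.asarray(partition.label_of_latitude(lat))
    tl = _tl_from_age(ages, rng)
    records = [
        CaptureRecord(id=f"L{i:04d}", capture_lon=float(lon[i]),
                      capture_lat=float(lat[i]),
                      capture_time=t_capture, age_days=int(ages[i]),
                      total_length_mm=float(tl[i]),
                      capture_region=str(capture_region[i]),
                      life_stage="larva")
        for i in range(n)
    ]
    truth = ScenarioTruth(
        individuals=pd.DataFrame({
            "id": [r.id for r in records],
            "role": "larva",
            "true_region": true_region,
            "capture_region": capture_region,
            "crossed": true_region != capture_region,
            "true_x": x0, "true_y": y0,
            "hatch_time": hatch_times,
            "age_days": ages, "tl_mm": tl,
        }),
        params={"n": n, "advect_fraction": advect_fraction,
                "north_fraction": north_fraction,
                "age_range": list(age_range), "seed": seed})
    return records, truth


def gen_juvenile_truth(n: int, mixture_north: float = 0.5,
                       partition: RegionPartition | None = None,
                       seed: int = 0) -> ScenarioTruth:
    """True natal regions for a mixed juvenile cohort (no trajectories).

    Juveniles are classified from their tags alone, so only their true
    hatch region matters; it is drawn Bernoulli(``mixture_north``).
    """
    partition = partition or RegionPartition()
    rng = np.random.default_rng(seed)
    north = rng.random(n) < mixture_north
    regions = np.where(north, partition.north_label, partition.south_label)
    df = pd.DataFrame({
        "id": [f"J{i:04d}" for i in range(n)],
        "role": "juvenile",
        "true_region": regions,
        "capture_region": "mixed",
        "age_days": rng.integers(60, 120, size=n),
        "tl_mm": rng.normal(55.0, 8.0, size=n),
    })
    return ScenarioTruth(individuals=df,
                         params={"n": n, "mixture_north": mixture_north,
                                 "seed": seed})


def gen_genotypes(truth: ScenarioTruth | pd.DataFrame, n_loci: int = 7,
                  alleles_per_locus: int = 8, F: float = 0.05,
                  seed: int = 0, label_by: str = "true_region",
                  unknown_roles=("juvenile",)) -> GenotypeTable:
    """Balding–Nichols genotypes for every individual in the truth table.

    Subpopulation allele frequencies are drawn per locus about shared
    ancestral frequencies with divergence parameter ``F``
    (Dirichlet(p·(1−F)/F); F = 0 means identical frequencies), and
    genotypes are drawn in Hardy–Weinberg proportions within each true
    region.  Individuals whose role is in ``unknown_roles`` are
    labelled "unknown" (their truth stays in the truth table).
    """
    if not 0 <= F < 0.5:
        raise ValueError("F must be in [0, 0.5)")
    df = truth.individuals if isinstance(truth, ScenarioTruth) else truth
    rng = np.random.default_rng(seed)
    regions = sorted(df["true_region"].unique())
    pop_freqs = {reg: [] for reg in regions}
    for _ in range(n_loci):
        anc = rng.dirichlet(np.ones(alleles_per_locus))
        for reg in regions:
            if F == 0:
                pop_freqs[reg].append(anc)
            else:
                pop_freqs[reg].append(
                    rng.dirichlet(anc * (1.0 - F) / F))
    n = len(df)
    calls = np.zeros((n, n_loci, 2), dtype=np.int32)
    for i, reg in enumerate(df["true_region"]):
        for j in range(n_loci):
            p = pop_freqs[reg][j]
            calls[i, j] = rng.choice(
                np.arange(1, alleles_per_locus + 1), size=2, p=p)
    labels = [
        "unknown" if role in unknown_roles else str(lab)
        for role, lab in zip(df["role"], df[label_by])]
    individuals = pd.DataFrame({
        "id": df["id"].to_numpy(),
        "population": labels,
        "year": df["hatch_time"].dt.year.to_numpy()
        if "hatch_time" in df and hasattr(df["hatch_time"], "dt")
        else 2006,
        "tl_mm": df["tl_mm"].to_numpy()
        if "tl_mm" in df else np.nan,
    })
    return GenotypeTable(individuals=individuals,
                         loci=[f"SYN{j + 1:02d}" for j in range(n_loci)],
                         calls=calls)


def gen_otolith(truth: ScenarioTruth | pd.DataFrame,
                element_params: dict | None = None,
                trend_slopes: dict | None = None, seed: int = 0,
                radius_per_day: float = 5.0, radius_at_hatch: float = 20.0,
                radius_noise: float = 5.0,
                standard_cv: dict | None = None,
                lod_pass_fraction: float = 1.0):
    """Region-specific otolith chemistry with a common size trend.

    Concentrations are Normal(region mean, region SD) plus
    slope · (radius − cohort mean radius), truncated at 0; otolith
    radius grows linearly with age.  Returns ``(table, standard_cv)``
    in the layout the otolith module reads (id, group, year, radius_um,
    <element>_ugg columns named by element, <element>_above_lod flags).
    """
    if element_params is None:
        element_params = DEFAULT_ELEMENT_PARAMS
    if trend_slopes is None:
        trend_slopes = DEFAULT_TREND_SLOPES
    standard_cv = standard_cv or {el: 5.0 for el in element_params}
    df = truth.individuals if isinstance(truth, ScenarioTruth) else truth
    rng = np.random.default_rng(seed)
    n = len(df)
    age = df["age_days"].to_numpy(dtype=float) if "age_days" in df \
        else np.full(n, 10.0)
    radius = radius_at_hatch + radius_per_day * age \
        + rng.normal(0.0, radius_noise, n)
    radius = np.maximum(radius, 1.0)
    out = pd.DataFrame({
        "id": df["id"].to_numpy(),
        "group": ["unknown" if r == "juvenile" else str(t)
                  for r, t in zip(df["role"], df["true_region"])],
        "true_region": df["true_region"].to_numpy(),
        "year": 2006,
        "radius_um": radius,
    })
    rbar = radius.mean()
    for el, by_region in element_params.items():
        mean = np.array([by_region[t][0] for t in df["true_region"]])
        sd = np.array([by_region[t][1] for t in df["true_region"]])
        conc = rng.normal(mean, sd) \
            + trend_slopes.get(el, 0.0) * (radius - rbar)
        out[el] = np.maximum(conc, 0.0)
        out[f"{el}_above_lod"] = rng.random(n) < lod_pass_fraction
    return out, dict(standard_cv)
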