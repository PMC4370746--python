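"""Microsatellite subpopulation statistics and assignment.

Covers the genetics arm of the pipeline: Hardy–Weinberg screening with
a Monte-Carlo exact test, the locus-reliability filter, Weir–Cockerham
F_ST, frequency-method likelihoods with leave-one-out self-assignment,
the Paetkau-style Monte-Carlo exclusion test, and the two-step
classification of mixed-population (juvenile) genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = 0
DEFAULT_FLOOR = 0.01


class PopulationLookupError(KeyError):
    pass


@dataclass
class GenotypeTable:
    """Diploid multilocus calls for a set of individuals.

    ``calls`` is (n_individuals, n_loci, 2) of positive integer allele
    identifiers, 0 = missing.  ``individuals`` carries id, population
    (a label or "unknown"), year and TL in mm.
    """

    individuals: pd.DataFrame
    loci: list
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L, p = self.calls.shape
        if p != 2:
            raise ValueError("calls must be diploid (last axis of size 2)")
        if L != len(self.loci) or n != len(self.individuals):
            raise ValueError("calls shape inconsistent with loci/individuals")
        if np.any(self.calls < 0):
            raise ValueError("allele identifiers must be non-negative")
        present = (self.calls != MISSING).any(axis=(1, 2))
        if n and not present.all():
            raise ValueError("every individual needs >=1 non-missing call")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    def population_index(self, population) -> np.ndarray:
        idx = np.flatnonzero(
            self.individuals["population"].to_numpy() == population)
        if idx.size == 0:
            raise PopulationLookupError(
                f"population {population!r} not in table")
        return idx

    def subset(self, rows) -> "GenotypeTable":
        rows = np.asarray(rows)
        return GenotypeTable(
            individuals=self.individuals.iloc[rows].reset_index(drop=True),
            loci=list(self.loci),
            calls=self.calls[rows])

    def select_loci(self, keep) -> "GenotypeTable":
        pos = [self.loci.index(l) for l in keep]
        return GenotypeTable(individuals=self.individuals.copy(),
                             loci=list(keep), calls=self.calls[:, pos])

    def relabel(self, labels_by_id: dict) -> "GenotypeTable":
        """Return a copy whose population labels follow ``labels_by_id``;
        individuals without an entry are dropped."""
        ids = self.individuals["id"].to_numpy()
        keep = np.array([i in labels_by_id for i in ids])
        sub = self.subset(np.flatnonzero(keep))
        sub.individuals["population"] = [
            labels_by_id[i] for i in sub.individuals["id"]]
        return sub


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies of one reference population.

    ``floor`` is the frequency substituted for alleles unseen in the
    reference so no multilocus likelihood is ever exactly zero
    (GENECLASS-style zero correction).
    """

    population: str
    loci: list
    frequencies: list            # per locus: dict allele -> frequency
    n_copies: np.ndarray         # gene copies counted per locus
    floor: float = DEFAULT_FLOOR

    def __post_init__(self):
        if not 0 < self.floor <= 0.05:
            raise ValueError("floor must be in (0, 0.05]")

    def freq(self, locus_idx: int, allele: int) -> float:
        f = self.frequencies[locus_idx].get(int(allele), 0.0)
        return f if f > 0 else self.floor


def allele_freqs(table: GenotypeTable, population,
                 floor: float = DEFAULT_FLOOR) -> AlleleFrequencies:
    """Relative allele counts over non-missing gene copies, per locus."""
    rows = table.population_index(population)
    calls = table.calls[rows]
    freqs = []
    n_copies = np.zeros(len(table.loci), dtype=int)
    for j in range(len(table.loci)):
        copies = calls[:, j, :].ravel()
        copies = copies[copies != MISSING]
        n_copies[j] = copies.size
        if copies.size:
            alleles, counts = np.unique(copies, return_counts=True)
            freqs.append({int(a): c / copies.size
                          for a, c in zip(alleles, counts)})
        else:
            freqs.append({})
    return AlleleFrequencies(population=str(population),
                             loci=list(table.loci), frequencies=freqs,
                             n_copies=n_copies, floor=floor)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte-Carlo)
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    locus: str
    population: str
    year: object
    p_value: float
    n_permutations: int
    significant: bool = False
    defined: bool = True


def _genotype_log_score(codes_sorted: np.ndarray) -> np.ndarray:
    """log[2^h / Π n_ij!] per row of row-sorted genotype codes.

    This is the permutation-variable part of the conditional probability
    of a genotype table given its allele counts, so ranking by it is
    equivalent to ranking by the conditional probability itself.
    """
    m, n = codes_sorted.shape
    idx = np.broadcast_to(np.arange(n), (m, n))
    new_run = np.ones((m, n), dtype=bool)
    new_run[:, 1:] = codes_sorted[:, 1:] != codes_sorted[:, :-1]
    run_start = np.maximum.accumulate(np.where(new_run, idx, 0), axis=1)
    within = idx - run_start + 1          # 1,2,..,count within each run
    log_fact = np.sum(np.log(within), axis=1)   # Σ log n_ij!
    return -log_fact


def hwe_exact_test(locus_calls: np.ndarray, n_permutations: int = 100_000,
                   seed: int = 0, locus: str = "", population: str = "",
                   year=None) -> HweResult:
    """Monte-Carlo exact test of Hardy–Weinberg proportions at one locus.

    The 2N observed gene copies are shuffled into N random genotypes;
    the p-value is the (add-one corrected) fraction of shuffled tables
    whose conditional probability given the allele counts is at most
    the observed table's.  Monomorphic loci return p = 1.
    """
    calls = np.asarray(locus_calls)
    calls = calls[(calls != MISSING).all(axis=1)]
    n = calls.shape[0]
    if n == 0:
        return HweResult(locus, population, year, float("nan"),
                         0, defined=False)
    copies = calls.ravel()
    if np.unique(copies).size < 2:
        return HweResult(locus, population, year, 1.0, 0)

    K = int(copies.max()) + 1

    def codes(pairs):             # genotype code: min*K + max
        lo = np.minimum(pairs[..., 0], pairs[..., 1])
        hi = np.maximum(pairs[..., 0], pairs[..., 1])
        return lo * K + hi

    def score(pairs):
        c = np.sort(codes(pairs), axis=-1)
        het = np.count_nonzero(
            pairs[..., 0] != pairs[..., 1], axis=-1)
        return het * np.log(2.0) + _genotype_log_score(
            c if c.ndim == 2 else c[None])

    obs = score(calls[None])[0]
    rng = np.random.default_rng(seed)
    # permute copies in blocks to bound memory
    n_le = 0
    done = 0
    block = max(1, min(n_permutations, 4_000_000 // max(2 * n, 1)))
    while done < n_permutations:
        m = min(block, n_permutations - done)
        perm = rng.permuted(
            np.broadcast_to(copies, (m, 2 * n)).copy(), axis=1)
        pairs = perm.reshape(m, n, 2)
        s = score(pairs)
        n_le += int(np.count_nonzero(s <= obs + 1e-12))
        done += m
    p = (n_le + 1) / (n_permutations + 1)
    return HweResult(locus, population, year, float(p), n_permutations)


def hwe_screen(table: GenotypeTable, n_permutations: int = 10_000,
               seed: int = 0, alpha: float = 0.05,
               bonferroni_divisor: int | None = None) -> pd.DataFrame:
    """HWE tests for every locus × population(-year) batch.

    Significance uses a Bonferroni-adjusted level alpha / divisor,
    the divisor defaulting to the number of loci tested per batch.
    """
    divisor = bonferroni_divisor or len(table.loci)
    rows = []
    pops = pd.unique(table.individuals["population"])
    years = (pd.unique(table.individuals["year"])
             if "year" in table.individuals else [None])
    rng = np.random.default_rng(seed)
    for pop in pops:
        for year in years:
            sel = table.individuals["population"].to_numpy() == pop
            if year is not None and not pd.isna(year) \
                    and "year" in table.individuals:
                sel &= (table.individuals["year"] == year).to_numpy()
            idx = np.flatnonzero(sel)
            if idx.size == 0:
                continue
            for j, locus in enumerate(table.loci):
                res = hwe_exact_test(
                    table.calls[idx, j], n_permutations,
                    seed=int(rng.integers(2**31)), locus=locus,
                    population=str(pop), year=year)
                res.significant = (res.defined
                                   and res.p_value < alpha / divisor)
                rows.append(res.__dict__)
    return pd.DataFrame(rows)


def filter_loci(flags: pd.DataFrame) -> list:
    """Apply the locus-reliability rule to HWE significance flags.

    ``flags`` needs columns locus, population, year, significant.  A
    locus is removed when it violates HWE in *both* populations within
    the same year, or in the *same* population across both (all) years;
    every other locus is retained, in input order.
    """
    flags = flags.copy()
    loci = list(pd.unique(flags["locus"]))
    pops = list(pd.unique(flags["population"]))
    years = list(pd.unique(flags["year"]))
    removed = set()
    sig = flags[flags["significant"].astype(bool)]
    for locus in loci:
        s = sig[sig["locus"] == locus]
        for year in years:
            pops_violating = set(s[s["year"] == year]["population"])
            if len(pops) >= 2 and set(pops) <= pops_violating:
                removed.add(locus)
        for pop in pops:
            years_violating = set(s[s["population"] == pop]["year"])
            if len(years) >= 2 and set(years) <= years_violating:
                removed.add(locus)
    return [l for l in loci if l not in removed]


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

def fst_weir_cockerham(table: GenotypeTable, pop_a, pop_b):
    """Weir–Cockerham (1984) θ between two populations.

    Returns ``(theta_multilocus, per_locus)`` where the multilocus value
    is the ratio of the a-components to the total variance components
    summed over loci and alleles.  Monomorphic loci contribute zero
    components; per-locus θ is NaN there.
    """
    idx = [table.population_index(pop_a), table.population_index(pop_b)]
    if any(i.size < 2 for i in idx):
        raise ValueError("both populations need >= 2 individuals")
    r = 2
    sum_a = 0.0
    sum_all = 0.0
    per_locus = {}
    for j, locus in enumerate(table.loci):
        calls = [table.calls[i, j] for i in idx]
        calls = [c[(c != MISSING).all(axis=1)] for c in calls]
        n_i = np.array([c.shape[0] for c in calls], dtype=float)
        if np.any(n_i < 1):
            per_locus[locus] = float("nan")
            continue
        alleles = np.unique(np.concatenate(
            [c.ravel() for c in calls]))
        if alleles.size < 2:
            per_locus[locus] = float("nan")
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        la = 0.0
        lall = 0.0
        for allele in alleles:
            p_i = np.array([
                np.mean(c == allele) for c in calls])   # over 2n copies
            h_i = np.array([
                np.mean((c == allele).sum(axis=1) == 1) for c in calls])
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            la += a
            lall += a + b + c
        per_locus[locus] = la / lall if lall != 0 else float("nan")
        sum_a += la
        sum_all += lall
    theta = sum_a / sum_all if sum_all != 0 else float("nan")
    return theta, per_locus


# ---------------------------------------------------------------------------
# frequency-method likelihoods and assignment
# ---------------------------------------------------------------------------

def frequency_likelihood(genotype: np.ndarray, freqs: AlleleFrequencies,
                         method: str = "frequency") -> float:
    """Log-likelihood of one multilocus genotype under a reference.

    Frequency method: homozygotes score p², heterozygotes 2pq, with the
    reference's floor substituted for unseen alleles; missing loci are
    skipped.  ``method="bayesian"`` uses Dirichlet-posterior mean
    frequencies (add 1/k pseudo-counts, k = alleles at the locus)
    instead of the raw relative counts.
    """
    genotype = np.asarray(genotype)
    loglik = 0.0
    scored = 0
    for j in range(genotype.shape[0]):
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        if a == MISSING or b == MISSING:
            continue
        if method == "bayesian":
            table = freqs.frequencies[j]
            k = max(len(table), 2)
            ncop = max(int(freqs.n_copies[j]), 0)
            pa = (table.get(a, 0.0) * ncop + 1.0 / k) / (ncop + 1.0)
            pb = (table.get(b, 0.0) * ncop + 1.0 / k) / (ncop + 1.0)
        else:
            pa = freqs.freq(j, a)
            pb = freqs.freq(j, b)
        loglik += np.log(pa * pb) + (np.log(2.0) if a != b else 0.0)
        scored += 1
    if scored == 0:
        raise ValueError("genotype has no scored loci")
    return float(loglik)


def _counts_by_pop(table, rows):
    """Per-locus allele Counters for a row subset (LOO bookkeeping)."""
    counts = []
    calls = table.calls[rows]
    for j in range(len(table.loci)):
        copies = calls[:, j, :].ravel()
        copies = copies[copies != MISSING]
        alleles, cnt = np.unique(copies, return_counts=True)
        counts.append(dict(zip(alleles.tolist(), cnt.tolist())))
    return counts


def _freqs_from_counts(counts, population, loci, floor):
    freqs = []
    n_copies = np.zeros(len(loci), dtype=int)
    for j, c in enumerate(counts):
        tot = sum(c.values())
        n_copies[j] = tot
        freqs.append({a: v / tot for a, v in c.items() if v > 0}
                     if tot else {})
    return AlleleFrequencies(population=population, loci=list(loci),
                             frequencies=freqs, n_copies=n_copies,
                             floor=floor)


def self_assign_loo(table: GenotypeTable, pop_a=None, pop_b=None,
                    floor: float = DEFAULT_FLOOR,
                    method: str = "frequency"):
    """Leave-one-out self-assignment of every reference individual.

    Each individual is withheld, its own population's frequencies are
    recomputed without it, and it is assigned to the arg-max of the two
    population log-likelihoods.  Returns ``(calls_df, accuracy_dict)``
    with per-population and overall percent correctly assigned.
    """
    pops = ([pop_a, pop_b] if pop_a is not None else
            list(pd.unique(table.individuals["population"])))
    if len(pops) != 2:
        raise ValueError("leave-one-out self-assignment needs 2 populations")
    idx = {p: table.population_index(p) for p in pops}
    counts = {p: _counts_by_pop(table, idx[p]) for p in pops}
    rows = []
    for p_self, p_other in ((pops[0], pops[1]), (pops[1], pops[0])):
        freqs_other = _freqs_from_counts(
            counts[p_other], p_other, table.loci, floor)
        for i in idx[p_self]:
            g = table.calls[i]
            loo = []
            for j in range(len(table.loci)):
                c = dict(counts[p_self][j])
                for al in g[j]:
                    if al != MISSING:
                        c[int(al)] = c.get(int(al), 0) - 1
                loo.append({a: v for a, v in c.items() if v > 0})
            freqs_self = _freqs_from_counts(loo, p_self, table.loci, floor)
            ll_self = frequency_likelihood(g, freqs_self, method)
            ll_other = frequency_likelihood(g, freqs_other, method)
            call = p_self if ll_self > ll_other else p_other
            if ll_self == ll_other:
                call = pops[0]          # deterministic tie rule
            rows.append({"id": table.individuals["id"].iloc[i],
                         "population": p_self, "call": call,
                         f"loglik_{pops[0]}":
                             ll_self if p_self == pops[0] else ll_other,
                         f"loglik_{pops[1]}":
                             ll_self if p_self == pops[1] else ll_other,
                         "correct": call == p_self})
    calls_df = pd.DataFrame(rows)
    accuracy = {p: 100.0 * calls_df[calls_df["population"] == p
                                    ]["correct"].mean() for p in pops}
    accuracy["overall"] = 100.0 * calls_df["correct"].mean()
    return calls_df, accuracy


# ---------------------------------------------------------------------------
# Monte-Carlo exclusion and juvenile classification
# ---------------------------------------------------------------------------

def _simulate_logliks(freqs: AlleleFrequencies, n_sim, rng,
                      scored_loci) -> np.ndarray:
    """Log-likelihoods of n_sim genotypes drawn from the reference."""
    total = np.zeros(n_sim)
    for j in scored_loci:
        table = freqs.frequencies[j]
        if not table:
            continue
        alleles = np.array(list(table.keys()))
        probs = np.array(list(table.values()))
        probs = probs / probs.sum()
        draw = rng.choice(probs.size, size=(n_sim, 2), p=probs)
        pa = probs[draw[:, 0]]
        pb = probs[draw[:, 1]]
        het = draw[:, 0] != draw[:, 1]
        total += np.log(pa * pb) + het * np.log(2.0)
    return total


def exclusion_test(genotype: np.ndarray, freqs: AlleleFrequencies,
                   n_sim: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo exclusion p-value of a genotype against a reference.

    Simulates ``n_sim`` genotypes from the reference allele frequencies
    (two gene copies per locus, loci the query actually scores) and
    returns the add-one-corrected fraction whose likelihood is at most
    the query's.  Small p means the genotype sits in the extreme lower
    tail — grounds to exclude the reference as the source.
    """
    genotype = np.asarray(genotype)
    scored = [j for j in range(genotype.shape[0])
              if genotype[j, 0] != MISSING and genotype[j, 1] != MISSING]
    obs = frequency_likelihood(genotype, freqs)
    rng = np.random.default_rng(seed)
    sims = _simulate_logliks(freqs, n_sim, rng, scored)
    return float((np.count_nonzero(sims <= obs + 1e-12) + 1)
                 / (n_sim + 1))


@dataclass
class JuvenileCall:
    id: str
    exclusion_p: dict              # population -> p-value
    status: str                    # excluded | assigned | failed
    assigned_population: str | None
    score_north: float             # relative likelihood toward pop_a


def classify_juveniles(juveniles: GenotypeTable, reference: GenotypeTable,
                       pop_a=None, pop_b=None,
                       exclude_below: float = 0.30, assign_at: float = 0.70,
                       n_sim: int = 10_000, seed: int = 0,
                       floor: float = DEFAULT_FLOOR):
    """Two-step mixed-population classification of unknown-origin fish.

    Step 1 excludes juveniles whose Monte-Carlo exclusion p-value is
    below ``exclude_below`` for *both* reference populations (they
    plausibly came from neither).  Step 2 scores the rest with the
    frequency method: with s = L_a/(L_a+L_b), s ≥ ``assign_at`` assigns
    to the first population, s ≤ 1−assign_at to the second, anything
    between is a failed assignment.  Returns ``(calls, summary)`` with
    the summary giving percent excluded / assigned each way / failed.
    """
    if reference.n == 0:
        raise ValueError("empty reference table")
    pops = ([pop_a, pop_b] if pop_a is not None else
            list(pd.unique(reference.individuals["population"])))
    if len(pops) != 2:
        raise ValueError("classification needs exactly 2 reference pops")
    freqs = {p: allele_freqs(reference, p, floor) for p in pops}
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(juveniles.n):
        g = juveniles.calls[i]
        jid = juveniles.individuals["id"].iloc[i]
        pvals = {p: exclusion_test(g, freqs[p], n_sim,
                                   seed=int(rng.integers(2**31)))
                 for p in pops}
        if max(pvals.values()) < exclude_below:
            calls.append(JuvenileCall(jid, pvals, "excluded", None,
                                      float("nan")))
            continue
        ll_a = frequency_likelihood(g, freqs[pops[0]])
        ll_b = frequency_likelihood(g, freqs[pops[1]])
        m = max(ll_a, ll_b)
        s = np.exp(ll_a - m) / (np.exp(ll_a - m) + np.exp(ll_b - m))
        if s >= assign_at:
            calls.append(JuvenileCall(jid, pvals, "assigned", pops[0],
                                      float(s)))
        elif s <= 1.0 - assign_at:
            calls.append(JuvenileCall(jid, pvals, "assigned", pops[1],
                                      float(s)))
        else:
            calls.append(JuvenileCall(jid, pvals, "failed", None, float(s)))
    n = len(calls)
    summary = {
        "n": n,
        "pct_excluded": 100.0 * sum(c.status == "excluded"
                                    for c in calls) / n if n else 0.0,
        f"pct_{pops[0]}": 100.0 * sum(c.assigned_population == pops[0]
                                      for c in calls) / n if n else 0.0,
        f"pct_{pops[1]}": 100.0 * sum(c.assigned_population == pops[1]
                                      for c in calls) / n if n else 0.0,
        "pct_failed": 100.0 * sum(c.status == "failed"
                                  for c in calls) / n if n else 0.0,
    }
    return calls, summary


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

def write_genepop(table: GenotypeTable, path, title="nataltrack export",
                  digits: int = 3) -> None:
    """Write the table in GENEPOP format (one pop block per label)."""
    lines = [title]
    lines.extend(str(l) for l in table.loci)
    pops = list(pd.unique(table.individuals["population"]))
    for pop in pops:
        lines.append("Pop")
        for i in table.population_index(pop):
            parts = [f"{table.calls[i, j, 0]:0{digits}d}"
                     f"{table.calls[i, j, 1]:0{digits}d}"
                     for j in range(len(table.loci))]
            lines.append(
                f"{table.individuals['id'].iloc[i]} ,  " + " ".join(parts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path, pop_names=None) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit alleles, 000…0 = missing)."""
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    raw = [ln for ln in raw if ln.strip()]
    if len(raw) < 3:
        raise ValueError("truncated GENEPOP file")
    body = raw[1:]
    loci = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    if i == len(body):
        raise ValueError("GENEPOP file has no Pop block")
    ids, pops, rows = [], [], []
    pop_idx = -1
    for ln in body[i:]:
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in ln:
            raise ValueError(f"malformed GENEPOP line: {ln!r}")
        ind_id, geno = ln.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{ind_id.strip()}: {len(fields)} genotypes for "
                f"{len(loci)} loci")
        digits = len(fields[0]) // 2
        row = [[int(f[:digits]), int(f[digits:])] for f in fields]
        ids.append(ind_id.strip())
        name = (pop_names[pop_idx] if pop_names else f"pop{pop_idx + 1}")
        pops.append(name)
        rows.append(row)
    individuals = pd.DataFrame({"id": ids, "population": pops,
                                "year": pd.NA, "tl_mm": np.nan})
    return GenotypeTable(individuals=individuals, loci=loci,
                         calls=np.array(rows, dtype=np.int32))
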