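"""Synthetic longitudinal RRBS cohorts with known per-site ground truth.

The generator emulates the statistical structure of a captive
Asian-elephant blood-methylation study: ~30 individuals spanning ages
0-56 years, a heavily female-biased sex ratio, a longitudinal subset
re-sampled over 1-14 year windows, and per-CpG methylated/total read
counts with negative-binomial coverage and sparse missingness.

Per-site truth follows a logit-linear age model: methylation probability
for sample *i* at site *j* is

    p_ij = expit(beta0_j + beta1_j * age_i + e_ij),   e_ij ~ N(0, sigma_site)

with beta1_j nonzero only for age-associated sites.  Constitutively
hyper-/hypomethylated sites (mean ratio outside [0.1, 0.9]) are planted so
that the downstream mean-methylation filter has real work to do.  Read
totals are negative-binomial, zeroed with a small missing probability;
methylated counts are binomial given the total and p_ij.

Every stream of randomness is derived from the single cohort seed and an
operation label, so partial re-runs are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .methyl_io import MethylationDataset, write_coverage_file

__all__ = ["CohortSpec", "generate_individuals", "generate_methylation",
           "simulate_cohort", "write_fixture", "read_fixture_truth"]

SITE_CLASSES = ("age_up", "age_down", "const_high", "const_low", "null")

# Observed age-class composition of the real cohort (calf/juvenile/subadult/
# adult/senior sample counts 7/4/41/30/9), used by the "elephant" age profile.
_ELEPHANT_CLASS_WEIGHTS = np.array([7, 4, 41, 30, 9], dtype=float)
_ELEPHANT_CLASS_BOUNDS = [(0.0, 1.0), (1.0, 5.0), (5.0, 20.0), (20.0, 50.0),
                          (50.0, 56.0)]

# Baseline logit-methylation distribution for null/age sites, calibrated so
# the mean ratio of sites surviving the [0.1, 0.9] filter is ~0.66.
_BASELINE_MU = 0.8
_BASELINE_SD = 0.8


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the elephant study design: 30 individuals aged 0-56,
    ~70% of them longitudinal with 2-6 samples each, 90% female, ~12% of
    sites age-associated (three quarters gaining methylation with age),
    and sparse missingness on negative-binomial coverage.
    """

    n_individuals: int = 30
    n_sites: int = 100_000
    p_age: float = 0.12
    p_const_high: float = 0.04
    p_const_low: float = 0.04
    frac_age_up: float = 288 / 389  # observed hyper:hypo split of clock sites
    age_range: tuple[float, float] = (0.0, 56.0)
    age_profile: str = "uniform"  # or "elephant"
    longitudinal_fraction: float = 0.7
    samples_per_individual: tuple[int, int] = (2, 6)  # longitudinal subset
    interval_range: tuple[float, float] = (0.5, 4.0)  # years between samples
    slope_range: tuple[float, float] = (0.03, 0.08)  # |beta1| per year, logit
    sigma_site: float = 0.3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    missing_prob: float = 0.01
    female_fraction: float = 0.9
    target_mean_methylation: float = 0.66
    seed: int = 0

    def __post_init__(self):
        p_sum = self.p_age + self.p_const_high + self.p_const_low
        if not (0 <= self.p_age <= 1 and 0 <= self.p_const_high <= 1
                and 0 <= self.p_const_low <= 1 and p_sum <= 1):
            raise ValueError("class proportions must lie in [0,1] and sum <= 1")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be non-degenerate or a point")
        if self.age_profile not in ("uniform", "elephant"):
            raise ValueError(f"unknown age_profile {self.age_profile!r}")
        if not 0 <= self.longitudinal_fraction <= 1:
            raise ValueError("longitudinal_fraction must be in [0,1]")
        if self.samples_per_individual[0] < 2:
            raise ValueError("longitudinal individuals need >= 2 samples")


def _rng(seed: int, op: str) -> np.random.Generator:
    """Substream keyed by (cohort seed, operation label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(op.encode())])
    )


def generate_individuals(spec: CohortSpec) -> pd.DataFrame:
    """Draw the sample table: individuals, sexes, ages at each sampling.

    Baseline ages are uniform on ``age_range`` (or drawn from the observed
    elephant age-class mixture); a random subset of individuals is
    longitudinal and receives extra samples at cumulative uniform
    intervals.  Returns a metadata frame with one row per blood sample.
    """
    rng = _rng(spec.seed, "individuals")
    n = spec.n_individuals
    sexes = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    if spec.age_profile == "elephant":
        w = _ELEPHANT_CLASS_WEIGHTS / _ELEPHANT_CLASS_WEIGHTS.sum()
        cls = rng.choice(len(w), size=n, p=w)
        base_ages = np.array(
            [rng.uniform(*_ELEPHANT_CLASS_BOUNDS[c]) for c in cls]
        )
    else:
        base_ages = rng.uniform(*spec.age_range, size=n)
    longitudinal = rng.random(n) < spec.longitudinal_fraction

    rows = []
    for i in range(n):
        ind = f"ind{i + 1:03d}"
        n_samp = (
            int(rng.integers(spec.samples_per_individual[0],
                             spec.samples_per_individual[1] + 1))
            if longitudinal[i] else 1
        )
        age = base_ages[i]
        for s in range(n_samp):
            if s > 0:
                age = age + rng.uniform(*spec.interval_range)
            rows.append(
                {
                    "sample_id": f"{ind}_s{s + 1}",
                    "individual_id": ind,
                    "sex": sexes[i],
                    "age_years": round(float(age), 4),
                }
            )
    return pd.DataFrame(rows)


def _site_truth(spec: CohortSpec) -> pd.DataFrame:
    rng = _rng(spec.seed, "sites")
    m = spec.n_sites
    u = rng.random(m)
    klass = np.full(m, "null", dtype=object)
    c1 = spec.p_age * spec.frac_age_up
    c2 = spec.p_age
    c3 = spec.p_age + spec.p_const_high
    c4 = c3 + spec.p_const_low
    klass[u < c1] = "age_up"
    klass[(u >= c1) & (u < c2)] = "age_down"
    klass[(u >= c2) & (u < c3)] = "const_high"
    klass[(u >= c3) & (u < c4)] = "const_low"

    mu = _BASELINE_MU + logit(spec.target_mean_methylation) - logit(0.66)
    beta0 = rng.normal(mu, _BASELINE_SD, size=m)
    beta0[klass == "const_high"] = logit(rng.uniform(0.92, 0.99,
                                                     (klass == "const_high").sum()))
    beta0[klass == "const_low"] = logit(rng.uniform(0.01, 0.08,
                                                    (klass == "const_low").sum()))
    beta1 = np.zeros(m)
    is_age = (klass == "age_up") | (klass == "age_down")
    mag = rng.uniform(*spec.slope_range, size=int(is_age.sum()))
    sign = np.where(klass[is_age] == "age_up", 1.0, -1.0)
    beta1[is_age] = sign * mag
    # centre age sites so their trajectory stays away from saturation
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    beta0[is_age] = rng.normal(0.0, 0.5, int(is_age.sum())) - beta1[is_age] * mid_age

    # site coordinates: ~20 contigs, unique even positions (pre-collapsed CpGs)
    n_contigs = min(20, m)
    contig = rng.integers(0, n_contigs, size=m)
    truth = pd.DataFrame(
        {
            "chrom": [f"scaf_{c + 1:02d}" for c in contig],
            "klass": klass,
            "beta0": beta0,
            "beta1": beta1,
            "sigma_site": spec.sigma_site,
        }
    )
    truth["pos"] = 0
    for c, grp in truth.groupby("chrom", sort=True):
        k = len(grp)
        pos = np.sort(rng.choice(np.arange(1, 30_000_000, 2), size=k,
                                 replace=False))
        truth.loc[grp.index, "pos"] = pos
    truth = truth.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    return truth[["chrom", "pos", "klass", "beta0", "beta1", "sigma_site"]]


def generate_methylation(
    spec: CohortSpec, samples: pd.DataFrame
) -> tuple[MethylationDataset, pd.DataFrame]:
    """Simulate counts for the given sample table; return (dataset, truth)."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    truth = _site_truth(spec)
    rng = _rng(spec.seed, "counts")
    ages = samples["age_years"].to_numpy(float)
    m, n = len(truth), len(samples)

    eta = truth["beta0"].to_numpy()[:, None] + np.outer(
        truth["beta1"].to_numpy(), ages
    )
    if spec.sigma_site > 0:
        eta = eta + rng.normal(0.0, spec.sigma_site, size=(m, n))
    p = expit(eta)

    disp = spec.coverage_dispersion
    nb_p = disp / (disp + spec.coverage_mean)
    total = rng.negative_binomial(disp, nb_p, size=(m, n))
    if spec.missing_prob > 0:
        total[rng.random((m, n)) < spec.missing_prob] = 0
    meth = rng.binomial(total, p)

    dataset = MethylationDataset(
        sites=truth[["chrom", "pos"]].copy(),
        samples=samples.reset_index(drop=True),
        meth=meth.astype(np.int64),
        total=total.astype(np.int64),
    )
    return dataset, truth


def simulate_cohort(spec: CohortSpec) -> tuple[MethylationDataset, pd.DataFrame]:
    """Full cohort draw: sample table plus count matrices and site truth."""
    samples = generate_individuals(spec)
    return generate_methylation(spec, samples)


def write_fixture(
    dataset: MethylationDataset,
    truth: pd.DataFrame,
    out_dir,
    spec: CohortSpec | None = None,
) -> dict[str, Path]:
    """Write a cohort as on-disk files: one coverage file per sample,
    metadata TSV, truth TSV, and a YAML echo of the generating parameters.

    Zero-total rows are written too, so reading the files back through
    ``methyl_io.assemble_dataset`` reproduces the dataset exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cov_dir = out_dir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for col, sid in enumerate(dataset.samples["sample_id"]):
        df = pd.DataFrame(
            {
                "chrom": dataset.sites["chrom"],
                "pos": dataset.sites["pos"],
                "meth": dataset.meth[:, col],
                "total": dataset.total[:, col],
            }
        )
        path = cov_dir / f"{sid}.cov"
        write_coverage_file(df, path)
        paths[sid] = path
    meta_path = out_dir / "metadata.tsv"
    dataset.samples.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    if spec is not None:
        spec_path = out_dir / "cohort_spec.yaml"
        with open(spec_path, "w") as fh:
            yaml.safe_dump(asdict(spec), fh, sort_keys=False)
        paths["spec"] = spec_path
    return paths


def read_fixture_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
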