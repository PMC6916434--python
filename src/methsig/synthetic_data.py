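"""Seeded generator of methylation cohorts with planted class structure.

The generator emulates the anatomy of a colon-carcinogenesis methylation
study on proportion-scale array data:

* a **CCN** (colon-cancer-neutral) probe class that drifts upward with age
  in every tissue, with per-probe drift rates modulated by lifestyle
  exposures (aspirin, hormone replacement therapy), and that is
  hypermethylated in *all* cancers;
* a **CIMP** probe class, low in healthy mucosa and drifting only slowly,
  that gains methylation specifically in serrated-pathway samples —
  moderately in sessile serrated adenomas/polyps (SSA/P) and strongly in
  CIMP cancers;
* a **hypo** class losing methylation in cancers, plus low/high background
  classes;
* batch and colon-location covariate shifts applied additively on the
  M (logit2) scale, then back-transformed;
* beta-distributed measurement noise with mean/concentration
  parameterization Beta(mu*phi, (1-mu)*phi), and detection-failure
  missingness masked completely at random.

Every draw flows from one seed through deterministic sub-streams, so the
same configuration always yields bit-identical cohorts, and the planted
truth (probe classes, drift rates, sample clusters) is returned alongside
the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import ProbeAnnotation, ProbeMatrix, SampleSheet, ValidationError
from .diffmeth import beta_to_m, m_to_beta

PROBE_CLASSES = ("background_low", "background_high", "CCN", "CIMP", "hypo")

CC_GROUPS = ("nonCIMP_CC", "CIMP_CC")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference cohort used throughout the test suite:
    2,000 probes (300 CCN, 300 CIMP, 100 hypo, 1,300 background), 100
    healthy-mucosa samples aged 40-80, 20 cancers per subtype, and 12 TA +
    12 SSA/P lesions with paired normals.  Effect sizes place the CIMP
    class at +0.17 beta in SSA/P and +0.28 in CIMP cancers (the observed
    median precursor-to-cancer progression), the CCN class at +0.30 in all
    cancers, and CCN drift at 0.03 beta per decade with CIMP probes
    drifting five-fold slower.
    """

    n_probes: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: {
            "background_low": 0.325,
            "background_high": 0.325,
            "CCN": 0.15,
            "CIMP": 0.15,
            "hypo": 0.05,
        }
    )
    baselines: dict = field(
        default_factory=lambda: {
            "background_low": 0.10,
            "background_high": 0.85,
            "CCN": 0.08,
            "CIMP": 0.10,
            "hypo": 0.90,
        }
    )
    group_sizes: dict = field(
        default_factory=lambda: {
            "HNM": 100,
            "nonCIMP_CC": 20,
            "CIMP_CC": 20,
            "TA": 12,
            "SSAP": 12,
        }
    )
    age_range: tuple = (40.0, 80.0)
    drift_rate_mean: float = 0.03   # beta per 10 years, CCN probes
    drift_rate_sd: float = 0.01
    cimp_drift_fraction: float = 0.2  # CIMP drift = fraction * CCN drift
    lifestyle_rate_multiplier: dict = field(
        default_factory=lambda: {"aspirin": 0.5, "hrt": 0.5}
    )
    lifestyle_prevalence: float = 0.3
    lifestyle_unknown_rate: float = 0.05
    effect_sizes: dict = field(
        default_factory=lambda: {
            "CCN_in_all_CC": 0.30,
            "CIMP_in_SSAP": 0.17,
            "CIMP_in_CIMP_CC": 0.28,
            "hypo_in_CC": -0.30,
        }
    )
    precision: float = 50.0           # beta concentration phi
    n_batches: int = 2
    batch_effect_sd: float = 0.2      # M scale
    location_effect_sd: float = 0.1   # M scale, proximal samples
    missing_rate: float = 0.02
    sex_probe_fraction: float = 0.02  # background probes placed on chrX/chrY
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")
        if set(self.class_fractions) != set(PROBE_CLASSES):
            raise ValidationError(f"class_fractions must cover {PROBE_CLASSES}")
        if self.precision <= 0:
            raise ValidationError("precision phi must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range must be increasing")
        for cls, base in self.baselines.items():
            if not 0.01 <= base <= 0.99:
                raise ValidationError(f"class {cls}: baseline {base} outside [0.01, 0.99]")
        for name, eff in self.effect_sizes.items():
            if not -1.0 < eff < 1.0:
                raise ValidationError(f"effect size {name} must lie in (-1, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig keys: {sorted(unknown)}")
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class TruthLabels:
    """Planted ground truth: per-probe class and drift rate, per-sample
    cluster (CIMP / nonCIMP for cancers, the group label otherwise)."""

    probe_class: pd.DataFrame   # index probe_id; columns: class, drift_rate
    sample_cluster: pd.DataFrame  # index sample_id; columns: cluster

    def probes_of(self, cls: str) -> set[str]:
        return set(self.probe_class.index[self.probe_class["class"] == cls])

    def drift_probes(self, min_rate: float = 0.0) -> set[str]:
        return set(self.probe_class.index[self.probe_class["drift_rate"] > min_rate])


def write_truth(truth: TruthLabels, path: str | Path) -> None:
    """Lossless TSV export of probe truth (class + drift rate)."""
    out = truth.probe_class.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_truth(path: str | Path, sample_cluster: pd.DataFrame | None = None) -> TruthLabels:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index.name = "probe_id"
    if sample_cluster is None:
        sample_cluster = pd.DataFrame(columns=["cluster"])
    return TruthLabels(df, sample_cluster)


def write_sample_truth(truth: TruthLabels, path: str | Path) -> None:
    out = truth.sample_cluster.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def _make_probes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = {}
    remaining = config.n_probes
    for i, cls in enumerate(PROBE_CLASSES):
        if i == len(PROBE_CLASSES) - 1:
            counts[cls] = remaining
        else:
            counts[cls] = int(round(config.class_fractions[cls] * config.n_probes))
            remaining -= counts[cls]
    classes = np.concatenate([[cls] * n for cls, n in counts.items()])
    probe_ids = [f"cg{i:07d}" for i in range(config.n_probes)]
    rates = np.zeros(config.n_probes)
    ccn = classes == "CCN"
    cimp = classes == "CIMP"
    rates[ccn] = np.clip(
        rng.normal(config.drift_rate_mean, config.drift_rate_sd, ccn.sum()), 1e-3, None
    )
    rates[cimp] = np.clip(
        rng.normal(
            config.drift_rate_mean * config.cimp_drift_fraction,
            config.drift_rate_sd * config.cimp_drift_fraction,
            cimp.sum(),
        ),
        1e-4,
        None,
    )
    return pd.DataFrame(
        {"class": classes, "drift_rate": rates},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def _make_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    prox_prob = {"HNM": 0.5, "nonCIMP_CC": 0.2, "CIMP_CC": 0.8, "TA": 0.2, "SSAP": 0.8}
    pair_counter = 0
    for group, size in config.group_sizes.items():
        for i in range(size):
            sid = f"{group}{i + 1:03d}"
            age = float(np.round(rng.uniform(*config.age_range), 1))
            loc = "proximal" if rng.random() < prox_prob[group] else "distal"
            batch = f"B{rng.integers(config.n_batches) + 1}"
            flags = {}
            for exposure in config.lifestyle_rate_multiplier:
                true_user = rng.random() < config.lifestyle_prevalence
                reported = "unknown" if rng.random() < config.lifestyle_unknown_rate else (
                    "yes" if true_user else "no"
                )
                flags[exposure] = (true_user, reported)
            row = {
                "sample_id": sid,
                "group": group,
                "age": age,
                "location": loc,
                "batch": batch,
                "aspirin_true": flags["aspirin"][0],
                "aspirin_user": flags["aspirin"][1],
                "hrt_true": flags["hrt"][0],
                "hrt_user": flags["hrt"][1],
                "pair_id": np.nan,
            }
            rows.append(row)
            if group in ("TA", "SSAP"):
                pair_counter += 1
                pid = f"P{pair_counter:03d}"
                row["pair_id"] = pid
                rows.append(
                    {
                        **row,
                        "sample_id": f"{group}{i + 1:03d}N",
                        "group": "paired_normal",
                        "pair_id": pid,
                        "batch": row["batch"],
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig | None = None) -> tuple[ProbeMatrix, SampleSheet, TruthLabels]:
    """Generate one cohort: beta matrix, sample sheet, and planted truth."""
    config = config or SimConfig()
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_probes = np.random.default_rng(streams[0])
    rng_samples = np.random.default_rng(streams[1])
    rng_covar = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    rng_missing = np.random.default_rng(streams[4])

    probes = _make_probes(config, rng_probes)
    samples = _make_samples(config, rng_samples)
    G, n = len(probes), len(samples)
    classes = probes["class"].to_numpy()
    rates = probes["drift_rate"].to_numpy()
    baselines = np.array([config.baselines[c] for c in classes])

    ages = samples["age"].to_numpy(dtype=float)
    groups = samples["group"].to_numpy()
    decades = (ages - config.age_range[0]) / 10.0
    mult = np.ones(n)
    for exposure, m in config.lifestyle_rate_multiplier.items():
        mult *= np.where(samples[f"{exposure}_true"].to_numpy(dtype=bool), m, 1.0)

    mu = np.tile(baselines[:, None], (1, n))
    drifting = np.isin(classes, ("CCN", "CIMP"))
    # lifestyle exposure suppresses age drift at every drifting CpG
    mu += np.where(drifting[:, None], rates[:, None] * decades[None, :] * mult[None, :], 0.0)

    in_cc = np.isin(groups, CC_GROUPS)
    eff = config.effect_sizes
    mu += np.where((classes == "CCN")[:, None] & in_cc[None, :], eff["CCN_in_all_CC"], 0.0)
    mu += np.where(
        (classes == "CIMP")[:, None] & (groups == "SSAP")[None, :], eff["CIMP_in_SSAP"], 0.0
    )
    mu += np.where(
        (classes == "CIMP")[:, None] & (groups == "CIMP_CC")[None, :],
        eff["CIMP_in_CIMP_CC"],
        0.0,
    )
    mu += np.where((classes == "hypo")[:, None] & in_cc[None, :], eff["hypo_in_CC"], 0.0)
    mu = np.clip(mu, 0.01, 0.99)

    # covariate shifts on the M scale, back-transformed
    batch_labels = sorted(samples["batch"].unique())
    batch_eff = rng_covar.normal(0.0, config.batch_effect_sd, size=(len(batch_labels), G))
    batch_idx = samples["batch"].map({b: i for i, b in enumerate(batch_labels)}).to_numpy()
    loc_eff = rng_covar.normal(0.0, config.location_effect_sd, size=G)
    is_prox = (samples["location"] == "proximal").to_numpy()
    m_shift = batch_eff[batch_idx].T + np.outer(loc_eff, is_prox)
    mu = m_to_beta(beta_to_m(mu, 1e-6) + m_shift)
    mu = np.clip(mu, 0.005, 0.995)

    phi = config.precision
    values = rng_noise.beta(mu * phi, (1.0 - mu) * phi)
    if config.missing_rate > 0:
        mask = rng_missing.random(size=values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = ProbeMatrix(list(probes.index), list(samples["sample_id"]), values, "beta")
    sheet_df = samples.drop(columns=["aspirin_true", "hrt_true"])
    sheet = SampleSheet(sheet_df)
    cluster = np.where(
        groups == "CIMP_CC", "CIMP", np.where(groups == "nonCIMP_CC", "nonCIMP", groups)
    )
    truth = TruthLabels(
        probes,
        pd.DataFrame({"cluster": cluster}, index=list(samples["sample_id"])),
    )
    return matrix, sheet, truth


def simulate_annotation(truth: TruthLabels, config: SimConfig | None = None) -> ProbeAnnotation:
    """Array-manifest-style annotation for a simulated cohort.

    Planted signal classes stay on autosomes; a small fraction of
    background probes is placed on chrX/chrY so the sex-chromosome filter
    has work to do.  Deterministic given the config seed.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    probe_ids = list(truth.probe_class.index)
    classes = truth.probe_class["class"].to_numpy()
    chroms = np.array([f"chr{rng.integers(1, 23)}" for _ in probe_ids], dtype=object)
    background = np.isin(classes, ("background_low", "background_high"))
    sexable = np.flatnonzero(background)
    n_sex = int(round(config.sex_probe_fraction * len(probe_ids)))
    sex_rows = rng.choice(sexable, size=min(n_sex, sexable.size), replace=False)
    chroms[sex_rows] = np.where(rng.random(sex_rows.size) < 0.5, "chrX", "chrY")
    positions = rng.integers(10_000, 100_000_000, size=len(probe_ids))
    df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "position": positions,
            "gene_symbols": [f"GENE{i // 4:05d}" for i in range(len(probe_ids))],
            "cgi_relation": rng.choice(["island", "shore", "shelf", "open_sea"], len(probe_ids)),
        }
    )
    return ProbeAnnotation(df)


def simulate_study(
    config: SimConfig | None = None,
) -> tuple[ProbeMatrix, SampleSheet, ProbeAnnotation, TruthLabels]:
    """Cohort plus matching annotation in one call."""
    config = config or SimConfig()
    matrix, sheet, truth = simulate_cohort(config)
    annotation = simulate_annotation(truth, config)
    return matrix, sheet, annotation, truth
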