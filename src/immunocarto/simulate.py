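"""Synthetic NanoString-like cohorts with planted immune-module structure.

The generator emulates the count structure of an nCounter immune panel:
~600 probes split into endogenous genes (7 planted immune modules plus
uninformative background), housekeeping genes, positive controls and
negative controls.  Each sample carries a lognormal technical depth
factor applied to every probe; each endogenous probe has a lognormal
baseline; disease identity shifts the log2 mean of the sample's
dominant-module genes by a configurable effect (with per-gene jitter),
and of subdominant-module genes by a configured fraction of that
effect.  Counting noise is negative binomial (gamma–Poisson) with a
common dispersion; an extra per-sample per-gene lognormal "biological"
noise term controls within-disease heterogeneity.

A :class:`CohortGenerator` freezes the gene-level parameters (module
membership, baselines, per-gene effect sizes) so that sentinel cohorts,
test cohorts, erythroderma-like query samples and pre/post treatment
pairs can all be drawn from the *same* synthetic assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .normalize import RawCounts

#: Canonical module names, in panel order.
MODULES = ("Th1", "Th2", "Th17", "IFN-I", "neutro", "macro", "eosino")

#: Myeloid sub-modules split by the neutrophilic / COVID-skin / Wells contrast.
MYELOID = ("neutro", "macro", "eosino")

#: Module expected to dominate each disease (used for threshold fitting
#: and for concordance checks during classification).
DISEASE_DOMINANT_MODULE = {
    "PsO": "Th17",
    "AD": "Th2",
    "LP": "Th1",
    "CLE": "IFN-I",
    "NeuD": "neutro",
    "Wells": "eosino",
    "COVID-skin": "macro",
}

#: Modules active at dominant level per disease, including the
#: co-dominant diseases; the module-positive sets for threshold fitting.
DISEASE_ACTIVE_MODULES = {
    **{d: (m,) for d, m in DISEASE_DOMINANT_MODULE.items()},
    "BP": ("Th2", "neutro", "macro", "eosino"),
    "DHR": ("Th2", "neutro", "macro", "eosino", "IFN-I"),
}


@dataclass(frozen=True)
class DiseaseProfile:
    """Generative profile of one disease.

    dominant     : modules activated at full effect (several names →
                   co-dominant disease, e.g. bullous pemphigoid)
    subdominant  : modules activated at ``subdominant_fraction`` of the
                   dominant effect
    strength     : optional per-profile override of subdominant_fraction
    """

    name: str
    n_samples: int
    dominant: tuple[str, ...] = ()
    subdominant: tuple[str, ...] = ()
    strength: float | None = None


def sentinel_panel() -> list[DiseaseProfile]:
    """Six model diseases plus healthy skin, at the study's sample sizes."""
    return [
        DiseaseProfile("LP", 12, ("Th1",)),
        DiseaseProfile("AD", 16, ("Th2",), ("Th1", "Th17")),
        DiseaseProfile("PsO", 25, ("Th17",), ("neutro", "IFN-I")),
        DiseaseProfile("NeuD", 10, ("neutro",)),
        DiseaseProfile("CLE", 12, ("IFN-I",)),
        DiseaseProfile("Wells", 3, ("eosino",)),
        DiseaseProfile("Healthy", 8),
    ]


def extended_panel() -> list[DiseaseProfile]:
    """Sentinels plus the macrophage-rich, co-dominant and healthy groups."""
    return sentinel_panel() + [
        DiseaseProfile("COVID-skin", 8, ("macro",)),
        DiseaseProfile("BP", 12, ("Th2", "neutro", "macro", "eosino")),
        DiseaseProfile("DHR", 10, ("Th2", "neutro", "macro", "eosino", "IFN-I")),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    diseases: tuple[DiseaseProfile, ...] = ()
    n_module_genes_per_module: int = 15
    n_background_genes: int = 480
    n_housekeeping: int = 15
    n_positive: int = 6
    n_negative: int = 8
    dominant_log2fc: float = 2.0
    log2fc_jitter_sd: float = 0.5
    subdominant_fraction: float = 0.4
    depth_sd: float = 0.3
    bio_sd: float = 0.3
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {
            "n_module_genes_per_module": self.n_module_genes_per_module,
            "n_background_genes": self.n_background_genes,
            "n_housekeeping": self.n_housekeeping,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        for name, val in sizes.items():
            if val <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {val}")
        if not 0.0 < self.subdominant_fraction < 1.0:
            raise ConfigurationError("subdominant_fraction must be in (0, 1)")
        for prof in self.diseases:
            if prof.n_samples <= 0:
                raise ConfigurationError(
                    f"disease {prof.name!r} has non-positive n_samples"
                )
            for m in prof.dominant + prof.subdominant:
                if m not in MODULES:
                    raise ConfigurationError(
                        f"unknown module {m!r} in disease profile {prof.name!r}"
                    )

    @property
    def n_probes(self) -> int:
        return (
            self.n_background_genes
            + len(MODULES) * self.n_module_genes_per_module
            + self.n_housekeeping
            + self.n_positive
            + self.n_negative
        )


def default_config(panel: str = "sentinel", seed: int = 0, **overrides) -> SimulationConfig:
    panels = {"sentinel": sentinel_panel, "extended": extended_panel}
    if panel not in panels:
        raise ConfigurationError(f"unknown panel {panel!r}")
    return SimulationConfig(diseases=tuple(panels[panel]()), seed=seed, **overrides)


@dataclass
class TruthLabels:
    """Ground truth of a generated cohort."""

    disease: pd.Series                       # sample -> generating disease
    module_genes: dict[str, list[str]]       # module -> planted gene list
    dominant: dict[str, tuple[str, ...]]     # sample -> true dominant modules
    codominant: dict[str, tuple[str, ...]]   # sample -> dominant set when >= 2
    depth: pd.Series                         # sample -> true depth factor
    gene_log2fc: pd.Series                   # module gene -> planted effect size


class CohortGenerator:
    """Frozen synthetic assay: gene-level parameters drawn once per seed.

    Cohorts, query samples and treatment pairs sampled from one generator
    share probe identities, baselines and per-gene effect sizes, so they
    live on the same measurement scale and can be mixed downstream.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.module_genes: dict[str, list[str]] = {
            m: [f"{m}_g{i + 1:02d}" for i in range(c.n_module_genes_per_module)]
            for m in MODULES
        }
        self.background_genes = [f"BG_{i + 1:04d}" for i in range(c.n_background_genes)]
        self.endogenous = [
            g for m in MODULES for g in self.module_genes[m]
        ] + self.background_genes
        self.housekeeping = [f"HK_{i + 1:02d}" for i in range(c.n_housekeeping)]
        self.positive = [f"POS_{chr(65 + i)}" for i in range(c.n_positive)]
        self.negative = [f"NEG_{chr(65 + i)}" for i in range(c.n_negative)]

        self.base_log2 = pd.Series(
            rng.normal(6.5, 1.5, size=len(self.endogenous)), index=self.endogenous
        )
        self.hk_log2 = pd.Series(
            rng.normal(9.0, 0.8, size=c.n_housekeeping), index=self.housekeeping
        )
        # titration-ladder-like fixed positive-control levels
        self.pos_log2 = pd.Series(
            np.linspace(5.0, 13.0, c.n_positive), index=self.positive
        )
        module_gene_ids = [g for m in MODULES for g in self.module_genes[m]]
        self.gene_log2fc = pd.Series(
            rng.normal(c.dominant_log2fc, c.log2fc_jitter_sd, size=len(module_gene_ids)),
            index=module_gene_ids,
        )

    # ------------------------------------------------------------------
    def annotation(self) -> pd.DataFrame:
        rows = []
        for m in MODULES:
            rows += [(g, "endogenous", m) for g in self.module_genes[m]]
        rows += [(g, "endogenous", "") for g in self.background_genes]
        rows += [(g, "housekeeping", "") for g in self.housekeeping]
        rows += [(g, "positive", "") for g in self.positive]
        rows += [(g, "negative", "") for g in self.negative]
        ann = pd.DataFrame(rows, columns=["probe_id", "class", "true_module"])
        return ann.set_index("probe_id")

    def _expected_log2(self, profile: DiseaseProfile) -> pd.Series:
        """Depth-1, noise-free expected log2 level of endogenous probes."""
        mu = self.base_log2.copy()
        frac = (
            profile.strength
            if profile.strength is not None
            else self.config.subdominant_fraction
        )
        for m in profile.dominant:
            genes = self.module_genes[m]
            mu[genes] += self.gene_log2fc[genes]
        for m in profile.subdominant:
            genes = self.module_genes[m]
            mu[genes] += frac * self.gene_log2fc[genes]
        return mu

    def expected_counts(self, profile: DiseaseProfile, depth: float = 1.0) -> pd.Series:
        """Expected counts for one sample: linear in the depth factor."""
        vals = {}
        vals.update((2.0 ** self._expected_log2(profile) * depth).to_dict())
        vals.update((2.0 ** self.hk_log2 * depth).to_dict())
        vals.update((2.0 ** self.pos_log2 * depth).to_dict())
        vals.update({g: 2.0 for g in self.negative})
        order = self.endogenous + self.housekeeping + self.positive + self.negative
        return pd.Series(vals).reindex(order)

    def _draw_counts(self, mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        alpha = self.config.nb_dispersion
        if alpha <= 0:
            return rng.poisson(mu)
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        return rng.poisson(lam)

    def sample_profiles(
        self,
        profiles: list[DiseaseProfile],
        rng: np.random.Generator,
        role: str = "sentinel",
        id_prefix: str = "S",
    ) -> tuple[RawCounts, TruthLabels]:
        """Draw samples for the given profiles with fresh noise."""
        c = self.config
        order = self.endogenous + self.housekeeping + self.positive + self.negative
        n_endo = len(self.endogenous)
        rows, sample_ids, diseases, depths = [], [], [], {}
        dominant: dict[str, tuple[str, ...]] = {}
        codominant: dict[str, tuple[str, ...]] = {}
        idx = 0
        for prof in profiles:
            mu_log2 = self._expected_log2(prof).to_numpy()
            for _ in range(prof.n_samples):
                idx += 1
                sid = f"{id_prefix}{idx:04d}_{prof.name}"
                depth = float(np.exp(rng.normal(0.0, c.depth_sd)))
                noise = rng.normal(0.0, c.bio_sd, size=n_endo)
                mu = np.empty(len(order))
                mu[:n_endo] = depth * 2.0 ** (mu_log2 + noise)
                mu[n_endo : n_endo + c.n_housekeeping] = depth * 2.0 ** self.hk_log2
                mu[
                    n_endo + c.n_housekeeping : n_endo + c.n_housekeeping + c.n_positive
                ] = depth * 2.0 ** self.pos_log2
                mu[-c.n_negative :] = 2.0
                rows.append(self._draw_counts(mu, rng))
                sample_ids.append(sid)
                diseases.append(prof.name)
                depths[sid] = depth
                dominant[sid] = prof.dominant
                codominant[sid] = prof.dominant if len(prof.dominant) >= 2 else ()

        counts = pd.DataFrame(
            np.asarray(rows, dtype=np.int64), index=sample_ids, columns=order
        )
        metadata = pd.DataFrame(
            {"disease": diseases, "role": role, "treatment": "", "response": ""},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        truth = TruthLabels(
            disease=pd.Series(diseases, index=sample_ids, name="disease"),
            module_genes={m: list(g) for m, g in self.module_genes.items()},
            dominant=dominant,
            codominant=codominant,
            depth=pd.Series(depths, name="depth"),
            gene_log2fc=self.gene_log2fc.copy(),
        )
        return RawCounts(counts, self.annotation(), metadata), truth


def generate_cohort(config: SimulationConfig) -> tuple[RawCounts, TruthLabels]:
    """Generate a full cohort from a config; bit-identical under one seed."""
    if not config.diseases:
        raise ConfigurationError("config defines no disease profiles")
    gen = CohortGenerator(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    return gen.sample_profiles(list(config.diseases), rng)


def generate_queries(
    gen: CohortGenerator,
    disease_counts: dict[str, int],
    seed: int,
    role: str = "erythroderma",
) -> tuple[RawCounts, TruthLabels]:
    """Draw query samples (e.g. erythroderma) reusing sentinel generative
    profiles with an independent noise draw."""
    known = {p.name: p for p in extended_panel()} | {
        p.name: p for p in gen.config.diseases
    }
    profiles = []
    for name, n in disease_counts.items():
        if name not in known:
            raise ConfigurationError(f"unknown disease profile {name!r}")
        profiles.append(replace(known[name], n_samples=n))
    rng = np.random.default_rng(seed)
    return gen.sample_profiles(profiles, rng, role=role, id_prefix="Q")


def generate_switch_pairs(
    gen: CohortGenerator,
    n_patients: int,
    seed: int,
    switched: bool = True,
) -> tuple[RawCounts, TruthLabels]:
    """Paired pre/post treatment samples for the module-switch scenario.

    Pre-treatment samples follow a Th2-dominant profile; post-treatment
    samples are Th1-dominant when ``switched`` (therapy-induced immune
    shift) and remain Th2-dominant otherwise.  Metadata carries
    ``patient`` and ``timepoint`` columns.
    """
    pre = DiseaseProfile("AD", n_patients, ("Th2",), ("Th1", "Th17"))
    post_name = "AD-switch" if switched else "AD"
    post_dom = ("Th1",) if switched else ("Th2",)
    post = DiseaseProfile(post_name, n_patients, post_dom)
    rng = np.random.default_rng(seed)
    raw_pre, truth_pre = gen.sample_profiles([pre], rng, role="pre", id_prefix="P")
    raw_post, truth_post = gen.sample_profiles([post], rng, role="post", id_prefix="T")
    counts = pd.concat([raw_pre.counts, raw_post.counts])
    meta = pd.concat([raw_pre.metadata, raw_post.metadata])
    meta["timepoint"] = ["pre"] * n_patients + ["post"] * n_patients
    meta["patient"] = [f"PT{i + 1:03d}" for i in range(n_patients)] * 2
    truth = TruthLabels(
        disease=pd.concat([truth_pre.disease, truth_post.disease]),
        module_genes=truth_pre.module_genes,
        dominant={**truth_pre.dominant, **truth_post.dominant},
        codominant={**truth_pre.codominant, **truth_post.codominant},
        depth=pd.concat([truth_pre.depth, truth_post.depth]),
        gene_log2fc=truth_pre.gene_log2fc,
    )
    return RawCounts(counts, gen.annotation(), meta), truth
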