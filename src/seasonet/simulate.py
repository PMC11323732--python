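"""Synthetic post-annotation metatranscriptomic communities with known truth.

The generator emulates the state of a coastal plankton metatranscriptome
after assembly, annotation and counting: monthly samples at several
stations over a 12-month cycle, taxa with single-peaked seasonal blooms
(circular Gaussian phenology), partially annotated transcripts with a
mixture of taxonomic identity levels, ERCC-style spike-ins at a ~1% read
share, planted KO co-expression modules driven by shared latent seasonal
signals, and species-level phototroph/heterotroph PFAM expression blocks.

Every planted quantity (bloom schedules, module labels and latents, true
molecules per liter, trophic labels) is recorded in a ``SyntheticTruth``
so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("diatom", "dinoflagellate", "haptophyte", "ctenophore", "copepod", "green_alga")
TROPHIC_CLASSES = ("phototroph", "heterotroph")
DEFAULT_STATIONS = ("120", "130", "330", "700", "780", "ZG02")
DEFAULT_MONTHS = (
    "2020-07", "2020-08", "2020-09", "2020-10", "2020-11", "2020-12",
    "2021-01", "2021-02", "2021-03", "2021-04", "2021-05", "2021-06",
)
SPIKE_IDS = ("ERCC-0001", "ERCC-0002", "ERCC-0003")
SPIKE_LENGTHS = (250, 750, 1500)
SPIKE_MOLECULES = (2.0e8, 5.0e7, 1.0e7)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic community.

    Defaults mirror the sampling design being emulated: six stations
    sampled monthly over one annual cycle, a ~1% spike-in read share, and
    planted structure sized to the analysis defaults (five modules of 80
    KOs against a 70-KO minimum module size; trophic block effect 5).
    """

    n_stations: int = 6
    months: tuple[str, ...] = DEFAULT_MONTHS
    n_taxa: int = 12
    transcripts_per_taxon: int = 2400
    n_kos: int = 800
    n_pathways: int = 40
    n_pfams: int = 1200
    bloom_peaks: tuple[int, ...] | None = None
    bloom_width: float = 1.5
    depth_mean: float = 200_000.0
    nb_dispersion: float = 0.3
    frac_unannotated: float = 0.2
    identity_mixture: tuple[float, float, float] = (0.6, 0.25, 0.15)
    spike_fraction: float = 0.01
    seed: int = 0
    # planted-structure knobs
    n_modules: int = 5
    module_size: int = 80
    transcripts_per_module_ko: int = 3
    module_expression_share: float = 0.2
    trophic_effect: float = 5.0

    def __post_init__(self) -> None:
        counts = {
            "n_stations": self.n_stations, "n_taxa": self.n_taxa,
            "transcripts_per_taxon": self.transcripts_per_taxon,
            "n_kos": self.n_kos, "n_pathways": self.n_pathways,
            "n_pfams": self.n_pfams, "n_modules": self.n_modules,
            "module_size": self.module_size,
            "transcripts_per_module_ko": self.transcripts_per_module_ko,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")
        if len(self.months) < 1:
            raise ValidationError("months must be non-empty")
        if self.bloom_width <= 0:
            raise ValidationError("bloom_width must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        for name, value in (
            ("frac_unannotated", self.frac_unannotated),
            ("spike_fraction", self.spike_fraction),
            ("module_expression_share", self.module_expression_share),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if any(p < 0 for p in self.identity_mixture) or not math.isclose(
            sum(self.identity_mixture), 1.0, abs_tol=1e-9
        ):
            raise ValidationError("identity_mixture must be non-negative and sum to 1")
        if self.bloom_peaks is not None:
            if len(self.bloom_peaks) != self.n_taxa:
                raise ValidationError("bloom_peaks must have one entry per taxon")
            if any(not 0 <= p < len(self.months) for p in self.bloom_peaks):
                raise ValidationError("bloom_peaks indices must be valid month indices")
        if self.n_modules * self.module_size > self.n_kos:
            raise ValidationError("planted modules cannot exceed the KO catalog")
        if self.trophic_effect <= 0:
            raise ValidationError("trophic_effect must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside a synthetic dataset."""

    taxon_bloom_schedule: pd.DataFrame  # taxon x month expected activity
    ko_module_labels: pd.Series         # planted KO -> module id (1-based)
    module_latents: pd.DataFrame        # module x sample latent (log2 scale)
    molecules_per_liter: pd.DataFrame   # biological transcript x sample
    expected_counts: pd.DataFrame       # all rows (incl. spikes) x sample
    trophic_labels: pd.Series           # taxon_id -> phototroph/heterotroph
    spike_recovery: pd.Series           # per-sample true k (reads per molecule*bp)


@dataclass
class SyntheticDataset:
    """A full post-annotation dataset plus its generating truth."""

    counts: pd.DataFrame        # transcript (incl. spike rows) x sample
    lengths: pd.Series          # effective length (bp) per row of counts
    annotations: pd.DataFrame   # transcript_id, taxon_id, lineage, percent_identity, ko_id, pfam_ids
    metadata: pd.DataFrame      # one row per sample
    spikes: pd.DataFrame        # spike_id, length_bp, molecules_added
    pathways: pd.DataFrame      # ko_id, pathway_id, pathway_name
    truth: SyntheticTruth


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def seasonal_profile(
    month_index: int,
    peak: int,
    width: float,
    amplitude: float,
    n_months: int,
) -> float:
    """Circular-Gaussian bloom activity at a given month.

    Distance is the circular month distance min(|m-p|, n_months-|m-p|);
    activity is amplitude * exp(-d^2 / (2 width^2)).
    """
    if n_months < 1:
        raise ValidationError("n_months must be >= 1")
    if width <= 0:
        raise ValidationError(f"width must be positive, got {width}")
    if amplitude <= 0:
        raise ValidationError(f"amplitude must be positive, got {amplitude}")
    d = abs(month_index - peak)
    d = min(d, n_months - d)
    return amplitude * math.exp(-(d * d) / (2.0 * width * width))


def sample_counts(
    expected_share: np.ndarray,
    depth: float,
    dispersion: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw gamma-Poisson read counts with mean depth*share.

    Var = mu + dispersion * mu^2; dispersion 0 degenerates to Poisson.
    """
    if dispersion < 0:
        raise ValidationError(f"dispersion must be >= 0, got {dispersion}")
    share = np.asarray(expected_share, dtype=float)
    if share.size and not math.isclose(float(share.sum()), 1.0, abs_tol=1e-6):
        raise ValidationError(f"shares must sum to 1, got {share.sum()}")
    if (share < 0).any():
        raise ValidationError("shares must be non-negative")
    rng = _rng(seed)
    if depth <= 0:
        return np.zeros(share.shape, dtype=np.int64)
    mu = depth * share
    if dispersion == 0:
        return rng.poisson(mu).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam).astype(np.int64)


def pfam_ids(n_pfams: int) -> list[str]:
    return [f"PF{i + 1:05d}" for i in range(n_pfams)]


def trophic_blocks(n_pfams: int) -> dict[str, list[str]]:
    """Fixed PFAM blocks marking the two trophic strategies.

    The first tenth of the PFAM catalog is the "photosynthesis" block, the
    second tenth the "degradation" block; the convention is shared between
    the training-set generator and the community generator so planted
    signals line up.
    """
    ids = pfam_ids(n_pfams)
    block = max(1, n_pfams // 10)
    return {"phototroph": ids[:block], "heterotroph": ids[block:2 * block]}


def make_trophic_training_set(
    n_per_class: int,
    n_pfams: int = 1200,
    effect: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Labelled PFAM expression profiles with planted trophic blocks.

    Phototroph profiles up-weight the photosynthesis block by (1+effect),
    heterotrophs the degradation block.  Profiles carry a wide global scale
    jitter so classifiers cannot rely on absolute library size.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if effect < 0:
        raise ValidationError(f"effect must be non-negative, got {effect}")
    rng = _rng(seed)
    ids = pfam_ids(n_pfams)
    blocks = trophic_blocks(n_pfams)
    block_idx = {
        label: np.array([ids.index(p) for p in members])
        for label, members in blocks.items()
    }
    rows, labels, names = [], [], []
    for label in TROPHIC_CLASSES:
        for j in range(n_per_class):
            v = rng.lognormal(mean=0.0, sigma=1.0, size=n_pfams)
            v[block_idx[label]] *= 1.0 + effect
            g = rng.lognormal(mean=math.log(100.0), sigma=1.0)
            rows.append(g * v)
            labels.append(label)
            names.append(f"train_{label[:3]}_{j:04d}")
    profiles = pd.DataFrame(np.vstack(rows), index=names, columns=ids)
    return profiles, pd.Series(labels, index=names, name="label"), blocks


def _orthogonal_month_latents(
    n_months: int, n_modules: int, rng: np.random.Generator
) -> np.ndarray:
    """Month-level latent trajectories with exactly zero cross-correlation."""
    g = rng.standard_normal((n_months, n_modules))
    q, _ = np.linalg.qr(g)
    q = q - q.mean(axis=0, keepdims=True)
    q = q / q.std(axis=0, keepdims=True)
    return q  # n_months x n_modules, unit variance per column


def simulate_ko_matrix(
    n_kos: int = 1000,
    n_samples: int = 60,
    n_modules: int = 5,
    module_size: int = 120,
    n_months: int = 12,
    member_noise_sd: float = 0.4,
    jitter_sd: float = 0.25,
    background_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """KO x sample TPM matrix with planted co-expression modules.

    Each module has a latent seasonal trajectory (orthogonalized across
    modules, so cross-module correlations are near zero); member KOs are
    noisy affine copies on the log2 scale; remaining KOs are independent
    background.  Returns (tpm, planted labels with 0 = background, module
    latents per sample).
    """
    if n_modules * module_size > n_kos:
        raise ValidationError("planted modules cannot exceed n_kos")
    rng = _rng(seed)
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    month_of = np.arange(n_samples) % n_months
    month_latents = _orthogonal_month_latents(n_months, n_modules, rng)
    latents = month_latents[month_of, :].T + rng.normal(
        0.0, jitter_sd, size=(n_modules, n_samples)
    )
    labels = np.zeros(n_kos, dtype=int)
    log2expr = np.empty((n_kos, n_samples))
    baseline = rng.uniform(5.0, 10.0, size=n_kos)
    for m in range(n_modules):
        members = slice(m * module_size, (m + 1) * module_size)
        labels[members] = m + 1
        gain = rng.uniform(0.7, 1.3, size=module_size)
        log2expr[members] = (
            baseline[members, None]
            + gain[:, None] * latents[m][None, :]
            + rng.normal(0.0, member_noise_sd, size=(module_size, n_samples))
        )
    background = labels == 0
    log2expr[background] = baseline[background, None] + rng.normal(
        0.0, background_sd, size=(int(background.sum()), n_samples)
    )
    tpm = pd.DataFrame(2.0 ** log2expr, index=kos, columns=samples)
    return (
        tpm,
        pd.Series(labels, index=kos, name="module"),
        pd.DataFrame(latents, index=range(1, n_modules + 1), columns=samples),
    )


def _identity_draw(rng: np.random.Generator, mixture: tuple[float, float, float], n: int) -> np.ndarray:
    """Percent identities from the three-way (>90 / 60-90 / <60) mixture."""
    cat = rng.choice(3, size=n, p=list(mixture))
    ident = np.empty(n)
    ident[cat == 0] = rng.uniform(90.5, 99.9, size=int((cat == 0).sum()))
    ident[cat == 1] = rng.uniform(61.0, 90.0, size=int((cat == 1).sum()))
    ident[cat == 2] = rng.uniform(30.0, 59.5, size=int((cat == 2).sum()))
    return ident


def simulate_community(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under the configured study design."""
    rng = _rng(config.seed)
    n_months = len(config.months)
    month_index = {m: i for i, m in enumerate(config.months)}

    stations = list(DEFAULT_STATIONS[: config.n_stations]) + [
        f"ST{i:02d}" for i in range(len(DEFAULT_STATIONS), config.n_stations)
    ]
    samples = [f"{st}_{mo}" for st in stations for mo in config.months]
    sample_month_idx = np.array([month_index[s.rsplit("_", 1)[1]] for s in samples])

    # --- taxa ---------------------------------------------------------------
    taxon_ids = [f"TX{i + 1:02d}" for i in range(config.n_taxa)]
    groups = [GROUPS[i % len(GROUPS)] for i in range(config.n_taxa)]
    lineages = [
        f"{groups[i]};Genus{i + 1:02d};Genus{i + 1:02d}_sp" for i in range(config.n_taxa)
    ]
    trophic = [TROPHIC_CLASSES[i % 2] for i in range(config.n_taxa)]
    if config.bloom_peaks is None:
        peaks = [(i * n_months) // config.n_taxa % n_months for i in range(config.n_taxa)]
    else:
        peaks = list(config.bloom_peaks)
    amplitude = rng.lognormal(0.0, 0.5, size=config.n_taxa)

    activity_by_month = np.array(
        [
            [
                seasonal_profile(m, peaks[i], config.bloom_width, amplitude[i], n_months)
                + 0.02 * amplitude[i]
                for m in range(n_months)
            ]
            for i in range(config.n_taxa)
        ]
    )  # taxon x month
    activity = activity_by_month[:, sample_month_idx]  # taxon x sample

    # --- taxon transcripts with planted trophic PFAM blocks ------------------
    ids = pfam_ids(config.n_pfams)
    blocks = trophic_blocks(config.n_pfams)
    block_idx = {
        label: np.array([ids.index(p) for p in members])
        for label, members in blocks.items()
    }
    pfam_intensity = rng.lognormal(0.0, 1.0, size=(config.n_taxa, config.n_pfams))
    for i in range(config.n_taxa):
        pfam_intensity[i, block_idx[trophic[i]]] *= 1.0 + config.trophic_effect

    t_ids, t_taxon, t_primary_pfam = [], [], []
    for i in range(config.n_taxa):
        order = rng.permutation(config.n_pfams)
        for j in range(config.transcripts_per_taxon):
            t_ids.append(f"{taxon_ids[i]}_t{j:05d}")
            t_taxon.append(i)
            t_primary_pfam.append(order[j % config.n_pfams])
    t_taxon = np.array(t_taxon)
    t_primary_pfam = np.array(t_primary_pfam)
    n_tax_tr = len(t_ids)
    t_weight = pfam_intensity[t_taxon, t_primary_pfam] * rng.lognormal(0.0, 0.3, n_tax_tr)
    taxon_intensity = t_weight[:, None] * activity[t_taxon, :]  # transcript x sample

    # pfam lists: primary plus occasional extras (annotation-style multi-domain)
    extra1 = rng.integers(0, config.n_pfams, size=n_tax_tr)
    extra2 = rng.integers(0, config.n_pfams, size=n_tax_tr)
    u = rng.random(n_tax_tr)
    pfam_lists = []
    for t in range(n_tax_tr):
        members = [ids[t_primary_pfam[t]]]
        if u[t] < 0.4:
            members.append(ids[extra1[t]])
        if u[t] < 0.1:
            members.append(ids[extra2[t]])
        pfam_lists.append(",".join(dict.fromkeys(members)))

    # --- planted KO modules, carried by dedicated transcripts ----------------
    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    n_module_kos = config.n_modules * config.module_size
    ko_module = np.zeros(config.n_kos, dtype=int)
    ko_module[:n_module_kos] = np.repeat(
        np.arange(1, config.n_modules + 1), config.module_size
    )
    month_latents = _orthogonal_month_latents(n_months, config.n_modules, rng)
    latents = month_latents[sample_month_idx, :].T + rng.normal(
        0.0, 0.25, size=(config.n_modules, len(samples))
    )

    m_ids, m_ko = [], []
    for k in range(n_module_kos):
        for r in range(config.transcripts_per_module_ko):
            m_ids.append(f"{ko_ids[k]}_t{r}")
            m_ko.append(k)
    m_ko = np.array(m_ko)
    m_module = ko_module[m_ko] - 1
    gain = rng.lognormal(0.0, 0.3, size=len(m_ids))
    slope = rng.uniform(0.7, 1.3, size=len(m_ids))
    module_intensity = gain[:, None] * 2.0 ** (
        slope[:, None] * latents[m_module, :]
        + rng.normal(0.0, 0.3, size=(len(m_ids), len(samples)))
    )
    # scale module expression to its configured share of the biological signal
    tax_total = taxon_intensity.sum()
    mod_total = module_intensity.sum()
    share = config.module_expression_share
    if mod_total > 0 and share > 0:
        module_intensity *= (share / (1.0 - share)) * tax_total / mod_total

    intensity = np.vstack([taxon_intensity, module_intensity])
    transcript_ids = t_ids + m_ids

    # --- lengths --------------------------------------------------------------
    lengths = np.clip(
        rng.lognormal(math.log(1000.0), 0.5, size=len(transcript_ids)), 200, 10000
    ).astype(int)

    # --- metadata -------------------------------------------------------------
    total_act = intensity.sum(axis=0)
    rel_act = total_act / total_act.mean()
    temp_phase = np.cos(2.0 * np.pi * sample_month_idx / n_months)
    winter = np.array(
        [
            seasonal_profile(m, (7 * n_months) // 12, 2.0, 1.0, n_months)
            for m in sample_month_idx
        ]
    )
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "station": [s.rsplit("_", 1)[0] for s in samples],
            "date": [s.rsplit("_", 1)[1] + "-15" for s in samples],
            "volume_filtered_l": np.round(
                50.0 * (1.0 - 0.6 * rel_act / (rel_act.max() + 1e-12))
                + rng.uniform(-2, 2, len(samples)),
                1,
            ).clip(5.0),
            "resuspension_volume_ml": np.round(rng.uniform(9, 45, len(samples)), 1),
            "extraction_input_ml": np.round(rng.uniform(1, 4, len(samples)), 2),
            "rna_yield_ng": np.round(rng.lognormal(math.log(1500), 0.4, len(samples)), 1),
            "temperature_c": np.round(
                12.3 + 10.2 * temp_phase + rng.normal(0, 0.6, len(samples)), 2
            ),
            "salinity_psu": np.round(
                32.0 + 1.5 * temp_phase + rng.normal(0, 0.3, len(samples)), 2
            ),
            "spm_mg_l": np.round(
                12.0 + 9.0 * winter + rng.lognormal(0, 0.4, len(samples)), 2
            ),
            "no3_umol_l": np.round(1.0 + 30.0 * winter * rng.lognormal(0, 0.2, len(samples)), 2),
            "po4_umol_l": np.round(0.1 + 1.5 * winter * rng.lognormal(0, 0.2, len(samples)), 3),
            "si_umol_l": np.round(1.0 + 15.0 * winter * rng.lognormal(0, 0.2, len(samples)), 2),
            "cell_density_per_l": np.round(1e4 * rel_act * rng.lognormal(0, 0.3, len(samples)), 0),
        }
    )
    metadata["library_input_ng"] = np.minimum(200.0, 0.8 * metadata["rna_yield_ng"]).round(1)

    # --- expected counts, spikes, truth ---------------------------------------
    scale = config.depth_mean * (1.0 - config.spike_fraction) / total_act.mean()
    e_bio = intensity * scale
    bio_tot = e_bio.sum(axis=0)
    spike_tot = bio_tot * config.spike_fraction / (1.0 - config.spike_fraction)
    spike_weight = np.array(SPIKE_MOLECULES) * np.array(SPIKE_LENGTHS)
    spike_alloc = spike_weight / spike_weight.sum()
    e_spike = spike_alloc[:, None] * spike_tot[None, :]
    expected = np.vstack([e_bio, e_spike])
    all_ids = transcript_ids + list(SPIKE_IDS)
    all_lengths = np.concatenate([lengths, np.array(SPIKE_LENGTHS)])

    k_true = spike_tot / float(spike_weight.sum())  # reads per molecule*bp
    meta_i = metadata.set_index("sample_id")
    extract = (meta_i["rna_yield_ng"] / meta_i["library_input_ng"]).to_numpy()
    residue = (meta_i["resuspension_volume_ml"] / meta_i["extraction_input_ml"]).to_numpy()
    vol = meta_i["volume_filtered_l"].to_numpy()
    molecules_per_liter = (
        e_bio / (k_true[None, :] * lengths[:, None]) * extract[None, :] * residue[None, :] / vol[None, :]
    )

    counts = np.empty_like(expected, dtype=np.int64)
    for j in range(len(samples)):
        tot = expected[:, j].sum()
        counts[:, j] = sample_counts(expected[:, j] / tot, tot, config.nb_dispersion, rng)

    # --- annotations -----------------------------------------------------------
    n_all_tr = len(transcript_ids)
    if config.frac_unannotated >= 1.0:
        tax_keep = np.zeros(n_all_tr, dtype=bool)
        ko_keep = np.zeros(n_all_tr, dtype=bool)
    else:
        tax_keep = rng.random(n_all_tr) < 1.0 - config.frac_unannotated
        ko_keep = rng.random(n_all_tr) < 1.0 - config.frac_unannotated
        ko_keep[n_tax_tr:] = True  # functional annotation always hits module carriers
    identity = _identity_draw(rng, config.identity_mixture, n_all_tr)

    non_module_kos = ko_ids[n_module_kos:]
    tax_ko = (
        rng.choice(non_module_kos, size=n_tax_tr)
        if non_module_kos
        else np.array([None] * n_tax_tr, dtype=object)
    )
    module_taxon = rng.integers(0, config.n_taxa, size=len(m_ids))

    rows = []
    for t in range(n_all_tr):
        is_module = t >= n_tax_tr
        taxon_i = int(module_taxon[t - n_tax_tr]) if is_module else int(t_taxon[t])
        keep_t = bool(tax_keep[t])
        keep_k = bool(ko_keep[t])
        ko = None
        if keep_k:
            ko = ko_ids[int(m_ko[t - n_tax_tr])] if is_module else str(tax_ko[t])
        rows.append(
            {
                "transcript_id": transcript_ids[t],
                "taxon_id": taxon_ids[taxon_i] if keep_t else None,
                "lineage": lineages[taxon_i] if keep_t else None,
                "percent_identity": round(float(identity[t]), 2) if keep_t else None,
                "ko_id": ko,
                "pfam_ids": (pfam_lists[t] if t < n_tax_tr else None) if keep_t else None,
            }
        )
    for sid in SPIKE_IDS:
        rows.append(
            {
                "transcript_id": sid, "taxon_id": None, "lineage": None,
                "percent_identity": None, "ko_id": None, "pfam_ids": None,
            }
        )
    annotations = pd.DataFrame(rows)

    # --- KO -> pathway map ------------------------------------------------------
    pathway_ids_ = [f"P{i + 1:05d}" for i in range(config.n_pathways)]
    prows = []
    for k, ko in enumerate(ko_ids):
        n_member = 1 + int(rng.random() < 0.3)
        for p in rng.choice(config.n_pathways, size=n_member, replace=False):
            prows.append(
                {
                    "ko_id": ko,
                    "pathway_id": pathway_ids_[int(p)],
                    "pathway_name": f"pathway_{int(p) + 1:02d}",
                }
            )
    pathways = pd.DataFrame(prows)

    truth = SyntheticTruth(
        taxon_bloom_schedule=pd.DataFrame(
            activity_by_month, index=taxon_ids, columns=list(config.months)
        ),
        ko_module_labels=pd.Series(
            ko_module[:n_module_kos], index=ko_ids[:n_module_kos], name="module"
        ),
        module_latents=pd.DataFrame(
            latents, index=range(1, config.n_modules + 1), columns=samples
        ),
        molecules_per_liter=pd.DataFrame(
            molecules_per_liter, index=transcript_ids, columns=samples
        ),
        expected_counts=pd.DataFrame(expected, index=all_ids, columns=samples),
        trophic_labels=pd.Series(trophic, index=taxon_ids, name="trophic"),
        spike_recovery=pd.Series(k_true, index=samples, name="k"),
    )
    return SyntheticDataset(
        counts=pd.DataFrame(counts, index=all_ids, columns=samples),
        lengths=pd.Series(all_lengths, index=all_ids, name="effective_length_bp"),
        annotations=annotations,
        metadata=metadata,
        spikes=pd.DataFrame(
            {
                "spike_id": SPIKE_IDS,
                "length_bp": SPIKE_LENGTHS,
                "molecules_added": SPIKE_MOLECULES,
            }
        ),
        pathways=pathways,
        truth=truth,
    )


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
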