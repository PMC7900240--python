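"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of a :class:`SimConfig`: the same
config (including its seed) yields identical output. The generators
emulate the statistical structure each analysis stage assumes — a shared
somatic truth set sampled by callers of differing sensitivity with added
false positives, negative-binomial count matrices with group effects,
piecewise-constant copy-number profiles with Gaussian noise, and a
four-type cohort with project-level signal — without attempting
read-level realism or sequence content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copynumber import Segment
from .somatic import CALLERS, VariantCall

__all__ = [
    "SimConfig",
    "simulate_caller_calls",
    "simulate_counts",
    "simulate_cn_profile",
    "simulate_multiomic_cohort",
    "write_vcf",
]

BASES = ("A", "C", "G", "T")
TOY_CONTIGS = {f"chr{i}": 10_000_000 for i in range(1, 23)}


@dataclass
class SimConfig:
    """Study conditions for all generators.

    Per-caller sensitivities default to the graded ladder
    (0.9, 0.8, 0.7, 0.6) across the four production callers; false
    positives are added per caller at ``caller_fp_rate`` times the truth
    size. Count matrices use a negative-binomial model with dispersion
    0.2; copy-number profiles are piecewise constant with Gaussian noise.
    """

    seed: int = 0
    n_samples: int = 90
    n_features: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 2000, "miRNA": 300, "methylation": 2000, "cnv": 400}
    )
    caller_sensitivities: dict[str, float] = field(
        default_factory=lambda: dict(zip(CALLERS, (0.9, 0.8, 0.7, 0.6)))
    )
    caller_fp_rate: float = 0.02
    n_truth_variants: int = 5000
    indel_fraction: float = 0.1
    nb_dispersion: float = 0.2
    n_probes: int = 100
    cn_breakpoints: list[tuple[int, float]] = field(default_factory=lambda: [(50, 1.0)])
    noise_sd: float = 0.1
    project_labels: list[str] = field(default_factory=lambda: ["PROJ-A", "PROJ-B", "PROJ-C"])

    def __post_init__(self) -> None:
        for caller, p in self.caller_sensitivities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sensitivity of {caller} outside [0,1]")
        if not 0.0 <= self.caller_fp_rate:
            raise ValueError("fp rate must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream named for its consumer."""
        return np.random.default_rng([self.seed, abs(hash_stream(stream)) % 2**31])


def hash_stream(name: str) -> int:
    # stable across processes (unlike builtin hash of str)
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 2**31
    return h


def _random_variant(rng: np.random.Generator, sample_id: str, caller: str, indel_fraction: float) -> VariantCall:
    contigs = list(TOY_CONTIGS)
    chrom = contigs[rng.integers(len(contigs))]
    pos = int(rng.integers(1, TOY_CONTIGS[chrom]))
    ref = BASES[rng.integers(4)]
    if rng.random() < indel_fraction:
        extra = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            alt, ref_out = ref + extra, ref  # insertion
        else:
            ref_out, alt = ref + extra, ref  # deletion
        return VariantCall(sample_id, caller, chrom, pos, ref_out, alt)
    alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    return VariantCall(sample_id, caller, chrom, pos, ref, alt)


def simulate_caller_calls(
    config: SimConfig, sample_id: str = "SAMPLE-1"
) -> tuple[dict[str, list[VariantCall]], dict[str, dict[str, list[VariantCall]]]]:
    """Shared truth set plus per-caller call sets.

    Each truth variant is independently emitted by each caller with that
    caller's sensitivity; per caller, ``fp_rate * n_truth`` false
    positives are added at random loci. Returns
    ``(truth, call_sets)`` with ``truth`` keyed by sample and
    ``call_sets`` keyed by caller then sample.
    """
    if not config.caller_sensitivities:
        raise ValueError("need at least one caller")
    rng = config.rng("caller_calls")
    truth = [
        _random_variant(rng, sample_id, "truth", config.indel_fraction)
        for _ in range(config.n_truth_variants)
    ]
    call_sets: dict[str, dict[str, list[VariantCall]]] = {}
    for caller, sens in config.caller_sensitivities.items():
        emitted = rng.random(len(truth)) < sens
        calls = [
            dataclasses.replace(t, caller=caller, filter={"PASS"}, gdc_filter=set())
            for t, keep in zip(truth, emitted)
            if keep
        ]
        n_fp = int(round(config.caller_fp_rate * config.n_truth_variants))
        calls.extend(
            _random_variant(rng, sample_id, caller, config.indel_fraction) for _ in range(n_fp)
        )
        call_sets[caller] = {sample_id: calls}
    return {sample_id: truth}, call_sets


def simulate_counts(
    config: SimConfig,
    data_type: str = "mRNA",
    groups: pd.Series | None = None,
    effect_size: float = 4.0,
    affected_frac: float = 0.1,
) -> pd.DataFrame:
    """Negative-binomial count matrix with optional group structure.

    Per-feature baseline means are log-normal; when ``groups`` is given
    (sample -> label), a seeded ``affected_frac`` of features get their
    mean multiplied by ``effect_size`` in one group each. Dispersion is
    ``config.nb_dispersion`` (NB variance mu + d*mu^2).
    """
    rng = config.rng(f"counts:{data_type}")
    n_feat = config.n_features.get(data_type, 2000)
    if groups is None:
        samples = [f"S{i:03d}" for i in range(config.n_samples)]
        group_arr = np.zeros(len(samples), dtype=int)
        n_groups = 1
    else:
        samples = list(groups.index)
        labels = sorted(set(groups))
        group_arr = np.array([labels.index(groups[s]) for s in samples])
        n_groups = len(labels)

    base_mu = rng.lognormal(mean=3.0, sigma=1.2, size=n_feat)
    mu = np.tile(base_mu[:, None], (1, len(samples)))
    if n_groups > 1:
        n_affected = int(round(affected_frac * n_feat))
        affected = rng.choice(n_feat, size=n_affected, replace=False)
        target_group = rng.integers(0, n_groups, size=n_affected)
        for f, g in zip(affected, target_group):
            mu[f, group_arr == g] *= effect_size

    d = config.nb_dispersion
    r = 1.0 / d
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    features = [f"{data_type}_F{i:05d}" for i in range(n_feat)]
    return pd.DataFrame(counts, index=features, columns=samples)


def simulate_cn_profile(
    config: SimConfig, chrom: str = "chr1"
) -> tuple[pd.DataFrame, list[Segment]]:
    """Piecewise-constant probe series plus the true segment list.

    ``config.cn_breakpoints`` is a sorted list of (probe index, new
    segment mean); the profile starts at mean 0. Probe positions are
    evenly spaced 1000 bp apart. Gaussian noise of sd ``noise_sd`` is
    added (0 gives the noiseless limit).
    """
    bps = sorted(config.cn_breakpoints)
    if any(not 0 < b < config.n_probes for b, _ in bps):
        raise ValueError("breakpoint indices must lie inside (0, n_probes)")
    rng = config.rng(f"cn:{chrom}")
    means = np.zeros(config.n_probes)
    bounds = [0] + [b for b, _ in bps] + [config.n_probes]
    levels = [0.0] + [m for _, m in bps]
    for lo, hi, m in zip(bounds[:-1], bounds[1:], levels):
        means[lo:hi] = m
    values = means + rng.normal(0.0, config.noise_sd, size=config.n_probes)
    pos = 1 + 1000 * np.arange(config.n_probes)
    series = pd.DataFrame(
        {
            "probe_id": [f"P{i:05d}" for i in range(config.n_probes)],
            "chrom": chrom,
            "pos": pos,
            "value": values,
        }
    )
    true_segments = [
        Segment(
            chrom=chrom,
            start=int(pos[lo]),
            end=int(pos[hi - 1]),
            num_probes=hi - lo,
            segment_mean=float(m),
        )
        for lo, hi, m in zip(bounds[:-1], bounds[1:], levels)
    ]
    return series, true_segments


def simulate_multiomic_cohort(
    config: SimConfig,
    signal_strength: float = 3.0,
    missing_rate: float = 0.02,
    high_missing_frac: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Four omic matrices on shared samples with project-level signal.

    Samples are split evenly over ``config.project_labels`` (>= 2
    required). mRNA/miRNA get group-shifted negative-binomial counts;
    methylation betas are logistic transforms of a Gaussian signal with
    project shifts, with missingness (a ``high_missing_frac`` fraction of
    probes is made >5% missing to exercise the filter); gene-level CNV is
    Gaussian around project-specific segment means. Returns
    ``(matrices, labels)`` with labels indexed by sample.
    """
    projects = config.project_labels
    if len(projects) < 2:
        raise ValueError("need at least two projects for cohort structure")
    per = config.n_samples // len(projects)
    samples, labels = [], []
    for j, proj in enumerate(projects):
        n = per if j < len(projects) - 1 else config.n_samples - per * (len(projects) - 1)
        for i in range(n):
            samples.append(f"{proj}-{i:03d}")
            labels.append(proj)
    labels = pd.Series(labels, index=samples, name="project")

    matrices: dict[str, pd.DataFrame] = {}
    for dtype in ("mRNA", "miRNA"):
        matrices[dtype] = simulate_counts(
            config, data_type=dtype, groups=labels,
            effect_size=signal_strength, affected_frac=0.2,
        )

    rng = config.rng("methylation")
    n_probe = config.n_features.get("methylation", 2000)
    group_idx = np.array([projects.index(p) for p in labels])
    shifts = rng.normal(0.0, 1.0, size=(n_probe, len(projects)))
    informative = rng.random(n_probe) < 0.3
    shifts[~informative] = 0.0
    z = rng.normal(0.0, 0.5, size=(n_probe, len(samples))) + shifts[:, group_idx]
    beta = 1.0 / (1.0 + np.exp(-z))
    miss = rng.random(beta.shape) < missing_rate
    n_high = int(round(high_missing_frac * n_probe))
    high_rows = rng.choice(n_probe, size=n_high, replace=False)
    miss[high_rows] |= rng.random((n_high, len(samples))) < 0.2
    beta[miss] = np.nan
    matrices["methylation"] = pd.DataFrame(
        beta, index=[f"cg{i:07d}" for i in range(n_probe)], columns=samples
    )

    rng = config.rng("cnv")
    n_gene = config.n_features.get("cnv", 400)
    cn_shifts = rng.normal(0.0, 0.5, size=(n_gene, len(projects)))
    informative = rng.random(n_gene) < 0.3
    cn_shifts[~informative] = 0.0
    cnv = cn_shifts[:, group_idx] + rng.normal(0.0, 0.2, size=(n_gene, len(samples)))
    matrices["cnv"] = pd.DataFrame(
        cnv, index=[f"GENE{i:05d}" for i in range(n_gene)], columns=samples
    )
    return matrices, labels


VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=SSC,Number=1,Type=Integer,Description="Somatic score">
##INFO=<ID=GDC_FILTER,Number=.,Type=String,Description="Pipeline filter labels">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="Ref fwd, ref rev, alt fwd, alt rev">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(calls: list[VariantCall], path: str) -> None:
    """Write calls as a minimal sorted two-sample (TUMOR/NORMAL) VCF."""
    contig_order = {c: i for i, c in enumerate(TOY_CONTIGS)}
    lines = [VCF_HEADER]
    for chrom in TOY_CONTIGS:
        lines.append(f"##contig=<ID={chrom},length={TOY_CONTIGS[chrom]}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n")
    for c in sorted(calls, key=lambda v: (contig_order.get(v.chrom, 99), v.pos, v.alt)):
        filt = ";".join(sorted(c.filter)) or "PASS"
        info_parts = []
        if c.ssc is not None:
            info_parts.append(f"SSC={c.ssc}")
        if c.gdc_filter:
            info_parts.append("GDC_FILTER=" + ",".join(sorted(c.gdc_filter)))
        info = ";".join(info_parts) or "."
        fmt_keys, tumor_vals, normal_vals = ["GT"], ["0/1"], ["0/0"]
        if c.tumor_depths is not None:
            fmt_keys.append("DP4")
            tumor_vals.append(",".join(str(d) for d in c.tumor_depths))
            normal_vals.append(".,.,.,.")
        if c.normal_alt_depth is not None:
            fmt_keys.append("AD")
            ref_d = (c.normal_depth or c.normal_alt_depth) - c.normal_alt_depth
            tumor_vals.append(".,.")
            normal_vals.append(f"{ref_d},{c.normal_alt_depth}")
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}\t"
            f"{':'.join(fmt_keys)}\t{':'.join(tumor_vals)}\t{':'.join(normal_vals)}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
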