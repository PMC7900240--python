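"""Multi-caller somatic variant filtering, aggregation, and comparison.

A tumor/normal pipeline emits one VCF per caller (MuSE, MuTect2,
VarScan2, SomaticSniper). This module ingests those call sets, applies
pipeline-level filters (SomaticSniper SSC removal, panel-of-normals
tagging, strand-bias tagging), aggregates calls to a project-level
MAF-style table with controlled/open access tiers, and computes the
cross-caller concordance and validated-variant recall analyses.

Two match modes exist throughout: *strict* (same chromosome, position and
alternative allele) and *loose* (same chromosome and overlapping
reference spans), the latter tolerating indels represented differently by
point-mutation-only callers.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from scipy import stats

logger = logging.getLogger(__name__)

CALLERS = ("MuSE", "MuTect2", "VarScan2", "SomaticSniper")

PON_LABEL = "panel_of_normals"
BIAS_LABEL = "strand_bias"

__all__ = [
    "VariantCall",
    "CALLERS",
    "read_somatic_vcf",
    "apply_ssc_filter",
    "tag_pon",
    "tag_strand_bias",
    "strict_match",
    "loose_match",
    "strict_key",
    "select_clean",
    "caller_partition",
    "recall_analysis",
    "build_maf",
    "mask_germline",
    "variant_class_ratios",
    "variant_class",
]


@dataclass
class VariantCall:
    """One caller's somatic call for one alternative allele.

    ``filter`` holds the caller's FILTER labels ("PASS" or reasons);
    ``gdc_filter`` collects pipeline-assigned labels (panel-of-normals,
    strand bias, ...). ``tumor_depths`` is (ref_fwd, ref_rev, alt_fwd,
    alt_rev) read support in the tumor.
    """

    sample_id: str
    caller: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter: set[str] = field(default_factory=lambda: {"PASS"})
    gdc_filter: set[str] = field(default_factory=set)
    ssc: int | None = None
    tumor_depths: tuple[int, int, int, int] | None = None
    normal_alt_depth: int | None = None
    normal_depth: int | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")

    @property
    def end(self) -> int:
        """Last reference base covered: pos + len(ref) - 1."""
        return self.pos + len(self.ref) - 1


def strict_key(v) -> tuple[str, int, str]:
    """(chrom, pos, alt) key used by strict matching."""
    return (v.chrom, v.pos, v.alt)


def strict_match(v1, v2) -> bool:
    """True iff chromosome, position and alternative allele all agree."""
    return strict_key(v1) == strict_key(v2)


def loose_match(v1, v2) -> bool:
    """True iff same chromosome and the reference spans overlap.

    The span of a variant is [pos, pos + len(ref) - 1]; an insertion
    occupies its anchor base. Symmetric and reflexive but not transitive.
    """
    return v1.chrom == v2.chrom and v1.pos <= v2.end and v2.pos <= v1.end


def read_somatic_vcf(path: str, caller: str, sample_id: str) -> list[VariantCall]:
    """Read a somatic VCF into VariantCall objects, one per (record, alt).

    Multi-allelic records are split before any filtering. Recognized
    per-record annotations: ``SSC`` (Somatic Score, INFO or tumor FORMAT),
    ``DP4``-style strand depths (tumor FORMAT), and ``GDC_FILTER`` (INFO,
    comma-separated labels).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        tumor = None
        for name in vcf.header.samples:
            if name.upper() in ("TUMOR", "PRIMARY") or tumor is None:
                tumor = name
        normal = next((n for n in vcf.header.samples if n != tumor), None)
        def info_get(rec, key):
            # pysam raises on lookups of keys missing from the header
            try:
                return rec.info[key] if key in rec.info else None
            except (KeyError, ValueError):
                return None

        for rec in vcf:
            filters = set(rec.filter.keys()) or {"PASS"}
            raw = info_get(rec, "GDC_FILTER")
            gdc = set() if raw is None else (set(raw) if isinstance(raw, tuple) else {raw})
            ssc = info_get(rec, "SSC")
            depths = None
            nad = None
            ndp = None
            if tumor is not None and tumor in rec.samples:
                fmt = rec.samples[tumor]
                if ssc is None and "SSC" in fmt:
                    ssc = fmt["SSC"]
                if "DP4" in fmt and fmt["DP4"] is not None:
                    d = fmt["DP4"]
                    depths = (int(d[0]), int(d[1]), int(d[2]), int(d[3]))
            if normal is not None and normal in rec.samples:
                nfmt = rec.samples[normal]
                if "AD" in nfmt and nfmt["AD"] is not None:
                    ad = nfmt["AD"]
                    if isinstance(ad, tuple) and len(ad) > 1 and ad[1] is not None:
                        nad = int(ad[1])
                if "DP" in nfmt and nfmt["DP"] is not None:
                    ndp = int(nfmt["DP"])
            for alt in rec.alts or ():
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        caller=caller,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        filter=set(filters),
                        gdc_filter=set(gdc),
                        ssc=int(ssc) if ssc is not None else None,
                        tumor_depths=depths,
                        normal_alt_depth=nad,
                        normal_depth=ndp,
                    )
                )
    return calls


def apply_ssc_filter(calls: Iterable[VariantCall], threshold: int = 25) -> list[VariantCall]:
    """Remove calls with Somatic Score below ``threshold`` (strictly).

    This is the one pipeline step that removes rather than tags: callers
    other than SomaticSniper carry no SSC and pass through untouched.
    """
    calls = list(calls)
    kept = [c for c in calls if c.ssc is None or c.ssc >= threshold]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("SSC filter removed %d call(s) below %d", removed, threshold)
    return kept


def tag_pon(
    calls: Iterable[VariantCall], pon: set[tuple[str, int, str]]
) -> list[VariantCall]:
    """Add the panel-of-normals label to calls strict-matching the panel.

    Nothing is removed; the label lands in ``gdc_filter``. The panel is a
    set of (chrom, pos, alt) keys.
    """
    calls = list(calls)
    for c in calls:
        if strict_key(c) in pon:
            c.gdc_filter.add(PON_LABEL)
    return calls


def strand_bias_pvalue(depths: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p for the 2x2 (ref fwd/rev vs alt fwd/rev) table."""
    rf, rr, af, ar = depths
    table = [[rf, rr], [af, ar]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def tag_strand_bias(calls: Iterable[VariantCall], alpha: float = 0.05) -> list[VariantCall]:
    """Tag calls whose alt reads show significant strand imbalance.

    A two-sided exact test of independence is run on the 2x2 table of
    (ref, alt) x (forward, reverse) tumor depths; p < alpha adds the
    strand-bias label to ``gdc_filter``. All-zero tables are skipped and
    logged, never tagged.
    """
    calls = list(calls)
    for c in calls:
        if c.tumor_depths is None:
            continue
        if sum(c.tumor_depths) == 0:
            logger.info("all-zero depth table at %s:%d, strand-bias test skipped", c.chrom, c.pos)
            continue
        if strand_bias_pvalue(c.tumor_depths) < alpha:
            c.gdc_filter.add(BIAS_LABEL)
    return calls


def variant_class(ref: str, alt: str) -> str:
    """SNP if both alleles are single bases, INS/DEL by length difference."""
    if len(ref) == len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "SNP"  # multi-base substitution of equal length


MAF_COLUMNS = [
    "project",
    "sample_id",
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "variant_class",
    "caller",
    "FILTER",
    "GDC_FILTER",
    "ssc",
    "normal_alt_depth",
]


def build_maf(calls: Iterable[VariantCall], project: str) -> pd.DataFrame:
    """Aggregate annotated calls into a controlled-access MAF-style table.

    One row per (sample, variant, caller); filter label sets are rendered
    as semicolon-joined strings. The table carries
    ``attrs["access"] == "controlled"``.
    """
    rows = []
    for c in calls:
        rows.append(
            {
                "project": project,
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "start": c.pos,
                "end": c.end,
                "ref": c.ref,
                "alt": c.alt,
                "variant_class": variant_class(c.ref, c.alt),
                "caller": c.caller,
                "FILTER": ";".join(sorted(c.filter)) or "PASS",
                "GDC_FILTER": ";".join(sorted(c.gdc_filter)),
                "ssc": c.ssc,
                "normal_alt_depth": c.normal_alt_depth,
            }
        )
    maf = pd.DataFrame(rows, columns=MAF_COLUMNS)
    maf.attrs["access"] = "controlled"
    return maf


def select_clean(maf: pd.DataFrame) -> pd.DataFrame:
    """Rows with FILTER == PASS and no pipeline filter labels ("clean" calls)."""
    mask = (maf["FILTER"] == "PASS") & (maf["GDC_FILTER"].fillna("") == "")
    out = maf[mask].copy()
    out.attrs.update(maf.attrs)
    return out


DEFAULT_GERMLINE_RULES: dict[str, object] = {
    "require_pass": True,
    "drop_gdc_tagged": True,
    "max_normal_alt_depth": 1,  # >= 2 alt reads in the normal -> dropped
    "max_normal_vaf": 0.02,
}
"""Default germline-masking rules for the open-access tier.

The production open-access criteria are unpublished; these defaults are
a plausible, deliberately stringent stand-in and every threshold is
configurable. Real somatic variants (e.g. at low normal coverage) can be
lost to this masking, which is why the controlled tier keeps everything.
"""


def mask_germline(
    maf: pd.DataFrame, rules: Mapping[str, object] | None = None
) -> pd.DataFrame:
    """Produce the open-access MAF by removing potential germline rows.

    The output is always a subset of the input; each removal is
    attributed to a rule in the log. An empty rule mapping returns the
    input unchanged (apart from the access tag).
    """
    rules = DEFAULT_GERMLINE_RULES if rules is None else dict(rules)
    keep = pd.Series(True, index=maf.index)
    removed_by: Counter[str] = Counter()

    if rules.get("require_pass"):
        bad = maf["FILTER"] != "PASS"
        removed_by["non_pass"] = int((keep & bad).sum())
        keep &= ~bad
    if rules.get("drop_gdc_tagged"):
        bad = maf["GDC_FILTER"].fillna("") != ""
        removed_by["gdc_tagged"] = int((keep & bad).sum())
        keep &= ~bad
    max_nad = rules.get("max_normal_alt_depth")
    if max_nad is not None and "normal_alt_depth" in maf.columns:
        nad = pd.to_numeric(maf["normal_alt_depth"], errors="coerce")
        bad = nad > max_nad
        removed_by["normal_alt_depth"] = int((keep & bad).sum())
        keep &= ~bad
    max_vaf = rules.get("max_normal_vaf")
    if max_vaf is not None and "normal_vaf" in maf.columns:
        vaf = pd.to_numeric(maf["normal_vaf"], errors="coerce")
        bad = vaf >= max_vaf
        removed_by["normal_vaf"] = int((keep & bad).sum())
        keep &= ~bad

    for rule, n in removed_by.items():
        if n:
            logger.info("germline masking: rule %s removed %d row(s)", rule, n)
    out = maf[keep].copy()
    out.attrs.update(maf.attrs)
    out.attrs["access"] = "open"
    return out


def _dedupe_strict(calls: Sequence) -> list:
    seen: set[tuple[str, int, str]] = set()
    out = []
    for c in calls:
        k = strict_key(c)
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def _matches_any(variant, calls_by_chrom: Mapping[str, list], matching: str) -> bool:
    if matching == "strict":
        return False  # handled via key sets by callers of this helper
    for other in calls_by_chrom.get(variant.chrom, ()):
        if loose_match(variant, other):
            return True
    return False


def _index_by_chrom(calls: Iterable) -> dict[str, list]:
    idx: dict[str, list] = {}
    for c in calls:
        idx.setdefault(c.chrom, []).append(c)
    return idx


def caller_partition(
    call_sets: Mapping[str, Sequence[VariantCall]], matching: str = "strict"
) -> pd.DataFrame:
    """Partition the union of all calls by the number of supporting callers.

    Every distinct variant in the union (strict-deduplicated) is assigned
    the count of call sets containing a match under the chosen mode.
    Loose matching is checked pairwise per caller set, without
    clustering, since span overlap is not transitive.

    Returns a DataFrame indexed by ``n_callers`` with ``count`` and
    ``fraction`` columns; fractions sum to 1.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two callers")
    if matching not in ("strict", "loose"):
        raise ValueError("matching must be 'strict' or 'loose'")

    union = _dedupe_strict([c for calls in call_sets.values() for c in calls])
    if matching == "strict":
        keysets = {name: {strict_key(c) for c in calls} for name, calls in call_sets.items()}
        counts = Counter(
            sum(strict_key(v) in ks for ks in keysets.values()) for v in union
        )
    else:
        indexes = {name: _index_by_chrom(calls) for name, calls in call_sets.items()}
        counts = Counter(
            sum(_matches_any(v, idx, "loose") for idx in indexes.values()) for v in union
        )
    total = sum(counts.values())
    ks = sorted(counts)
    df = pd.DataFrame(
        {
            "count": [counts[k] for k in ks],
            "fraction": [counts[k] / total for k in ks],
        },
        index=pd.Index(ks, name="n_callers"),
    )
    return df


def _truth_matched(
    truth_variant,
    caller_keyset: set[tuple[str, int, str]],
    caller_index: Mapping[str, list],
    matching: str,
) -> bool:
    if matching == "strict":
        return strict_key(truth_variant) in caller_keyset
    return _matches_any(truth_variant, caller_index, "loose")


def recall_analysis(
    truth: Mapping[str, Sequence],
    call_sets: Mapping[str, Mapping[str, Sequence[VariantCall]]],
    matching: str = "strict",
) -> dict[str, pd.DataFrame]:
    """Recall of validated variants per caller and per caller combination.

    Parameters
    ----------
    truth
        sample_id -> sequence of validated variants (objects with chrom /
        pos / ref / alt, e.g. VariantCall or any namedtuple-alike).
    call_sets
        caller -> (sample_id -> calls).
    matching
        "strict" or "loose".

    Returns a dict with:

    - ``per_caller``: recall per (sample, caller) plus a pooled row per
      caller (pooled over all truth variants).
    - ``by_k``: distribution of truth variants by the number of callers
      recalling them, including the zero bin; fractions sum to 1.
    - ``combinations``: for every non-empty caller subset, the recall of
      the union of its call sets (monotone in subset size).

    Samples with an empty truth set are excluded and logged.
    """
    callers = list(call_sets)
    samples = [s for s, tv in truth.items() if len(tv) > 0]
    skipped = [s for s in truth if s not in samples]
    for s in skipped:
        logger.info("sample %s has empty truth set; excluded from recall", s)

    per_caller_rows = []
    # per truth variant: set of callers that recalled it
    recalled_by: list[frozenset[str]] = []
    pooled_hits = Counter()
    pooled_total = 0

    for sample in samples:
        tvars = list(truth[sample])
        pooled_total += len(tvars)
        keysets = {}
        indexes = {}
        for caller in callers:
            calls = list(call_sets[caller].get(sample, ()))
            keysets[caller] = {strict_key(c) for c in calls}
            indexes[caller] = _index_by_chrom(calls)
        sample_hits = {caller: 0 for caller in callers}
        for tv in tvars:
            who = frozenset(
                caller
                for caller in callers
                if _truth_matched(tv, keysets[caller], indexes[caller], matching)
            )
            recalled_by.append(who)
            for caller in who:
                sample_hits[caller] += 1
                pooled_hits[caller] += 1
        for caller in callers:
            per_caller_rows.append(
                {
                    "sample_id": sample,
                    "caller": caller,
                    "n_truth": len(tvars),
                    "n_recalled": sample_hits[caller],
                    "recall": sample_hits[caller] / len(tvars),
                }
            )
    for caller in callers:
        per_caller_rows.append(
            {
                "sample_id": "__pooled__",
                "caller": caller,
                "n_truth": pooled_total,
                "n_recalled": pooled_hits[caller],
                "recall": pooled_hits[caller] / pooled_total if pooled_total else float("nan"),
            }
        )
    per_caller = pd.DataFrame(per_caller_rows)

    k_counts = Counter(len(who) for who in recalled_by)
    ks = list(range(len(callers) + 1))
    total = len(recalled_by)
    by_k = pd.DataFrame(
        {
            "count": [k_counts.get(k, 0) for k in ks],
            "fraction": [k_counts.get(k, 0) / total if total else float("nan") for k in ks],
        },
        index=pd.Index(ks, name="n_callers"),
    )

    combo_rows = []
    for r in range(1, len(callers) + 1):
        for combo in itertools.combinations(callers, r):
            cset = set(combo)
            hits = sum(1 for who in recalled_by if who & cset)
            combo_rows.append(
                {
                    "callers": "+".join(combo),
                    "k": r,
                    "n_truth": total,
                    "recall": hits / total if total else float("nan"),
                }
            )
    combinations = pd.DataFrame(combo_rows)
    return {"per_caller": per_caller, "by_k": by_k, "combinations": combinations}


def variant_class_ratios(maf: pd.DataFrame) -> pd.DataFrame:
    """Per-sample INS/SNP and DEL/SNP count ratios.

    A tenfold jump in INS/SNP relative to peers flags whole-genome-
    amplified libraries, whose chimeric reads masquerade as insertions.
    Samples with zero SNPs get NaN ratios and ``undefined=True``.
    """
    rows = []
    for sample, grp in maf.groupby("sample_id"):
        counts = grp["variant_class"].value_counts()
        snp = int(counts.get("SNP", 0))
        ins = int(counts.get("INS", 0))
        dele = int(counts.get("DEL", 0))
        undefined = snp == 0
        rows.append(
            {
                "sample_id": sample,
                "n_snp": snp,
                "n_ins": ins,
                "n_del": dele,
                "ins_snp_ratio": ins / snp if snp else float("nan"),
                "del_snp_ratio": dele / snp if snp else float("nan"),
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
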