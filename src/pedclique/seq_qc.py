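"""Sequence-variant QC: a generalized Mendelian check via IBD2 segments.

Classical Mendelian checks compare parents and offspring.  This check
instead uses every pair of sequenced individuals: inside an IBD2 segment —
a region where two individuals inherited *both* chromosomal segments from
common ancestors — their genotypes must agree, so a genotype mismatch
there implies a genotyping error in one of them.  For a class of variants
the discordance rate is total mismatches / total covering pairs, and
per-class call-rate cutoffs turn this into a pass/fail filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING
from .imputation import VariantRecord

# (singleton, rs_known, type) -> call-rate cutoff: pass iff call rate > cutoff.
# Only novel singleton insertions get the relaxed 0.9 cutoff among
# singletons; among non-singletons, known (rs) variants get 0.9 and novel
# ones 0.99.
DEFAULT_CUTOFFS: dict[tuple[bool, bool, str], float] = {
    (False, True, "SNV"): 0.9,
    (False, True, "insertion"): 0.9,
    (False, True, "deletion"): 0.9,
    (False, False, "SNV"): 0.99,
    (False, False, "insertion"): 0.99,
    (False, False, "deletion"): 0.99,
    (True, True, "SNV"): 0.99,
    (True, True, "insertion"): 0.99,
    (True, True, "deletion"): 0.99,
    (True, False, "SNV"): 0.99,
    (True, False, "insertion"): 0.9,
    (True, False, "deletion"): 0.99,
}


@dataclass(frozen=True)
class VariantClass:
    singleton: bool
    rs_known: bool
    variant_type: str  # SNV / insertion / deletion

    def __str__(self) -> str:
        return (f"{'singleton' if self.singleton else 'non-singleton'}/"
                f"{'RS' if self.rs_known else 'novel'}/{self.variant_type}")


def classify_variant(v: VariantRecord) -> VariantClass:
    """Class by singleton status (exactly one alt allele among non-missing
    sequenced genotypes), dbSNP novelty, and ref/alt length type."""
    return VariantClass(v.singleton, v.rs_known, v.variant_type)


def ibd2_discordance(v: VariantRecord, ibd2_by_pair: Mapping[tuple[str, str],
                     dict[int, list[tuple[int, int]]]],
                     sequenced_ids: Sequence[str],
                     position_of: "callable") -> tuple[int, int]:
    """(n covering pairs with both genotypes called, n discordant).

    ``ibd2_by_pair`` maps a sequenced sample pair to per-chromosome IBD2
    marker intervals; ``position_of(v)`` maps a variant to a (chrom, marker
    index) locating it on the interval scale.
    """
    chrom, midx = position_of(v)
    seq_index = {s: i for i, s in enumerate(sequenced_ids)}
    n_pairs = n_disc = 0
    for (a, b), per_chrom in ibd2_by_pair.items():
        ivals = per_chrom.get(chrom)
        if not ivals:
            continue
        if not any(s <= midx < e for s, e in ivals):
            continue
        ga = v.genotypes[seq_index[a]]
        gb = v.genotypes[seq_index[b]]
        if ga == MISSING or gb == MISSING:
            continue
        n_pairs += 1
        n_disc += int(ga != gb)
    return n_pairs, n_disc


def class_discordance_rate(variants: Sequence[VariantRecord],
                           ibd2_by_pair, sequenced_ids, position_of
                           ) -> tuple[float | None, int, int]:
    """Pooled discordance rate over a variant class: sum of discordances /
    sum of covering pairs; None when no pairs."""
    tot_pairs = tot_disc = 0
    for v in variants:
        n_p, n_d = ibd2_discordance(v, ibd2_by_pair, sequenced_ids, position_of)
        tot_pairs += n_p
        tot_disc += n_d
    rate = tot_disc / tot_pairs if tot_pairs else None
    return rate, tot_pairs, tot_disc


def apply_class_cutoffs(variants: Sequence[VariantRecord],
                        cutoffs: Mapping[tuple[bool, bool, str], float] | None = None,
                        high_quality: Sequence[bool] | None = None
                        ) -> list[bool]:
    """Pass/fail per variant: pass iff call rate strictly exceeds the
    class's cutoff (and the optional high-quality prerequisite holds)."""
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    out = []
    for i, v in enumerate(variants):
        cls = classify_variant(v)
        key = (cls.singleton, cls.rs_known, cls.variant_type)
        if key not in cutoffs:
            raise KeyError(f"no call-rate cutoff configured for class {cls}")
        ok = v.call_rate > cutoffs[key]
        if high_quality is not None:
            ok = ok and bool(high_quality[i])
        out.append(ok)
    return out


def qc_summary_table(variants: Sequence[VariantRecord], ibd2_by_pair,
                     sequenced_ids, position_of,
                     cutoffs=None):
    """Per-class summary: cutoff, discordance rate, counts, pass counts."""
    import pandas as pd

    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    passes = apply_class_cutoffs(variants, cutoffs)
    rows = []
    by_class: dict[VariantClass, list[int]] = {}
    for i, v in enumerate(variants):
        by_class.setdefault(classify_variant(v), []).append(i)
    for cls in sorted(by_class, key=str):
        idx = by_class[cls]
        rate, n_pairs, n_disc = class_discordance_rate(
            [variants[i] for i in idx], ibd2_by_pair, sequenced_ids, position_of)
        rows.append({
            "class": str(cls),
            "cutoff": cutoffs[(cls.singleton, cls.rs_known, cls.variant_type)],
            "discordance_rate": rate,
            "ibd2_pairs": n_pairs,
            "discordances": n_disc,
            "n_variants": len(idx),
            "n_pass": sum(passes[i] for i in idx),
        })
    return pd.DataFrame(rows)
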