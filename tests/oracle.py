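"""Independent straight-line reimplementation of the filtering rules.

Deliberately written without importing anything from the package's
filtering module: every rule is spelled out inline, so agreement between
this oracle and ``filter_variant`` is a meaningful cross-check rather
than a tautology.
"""

from __future__ import annotations

import numpy as np

LOF_LABELS = {
    "transcript_ablation", "essential_splice_site", "frameshift_indel",
    "stop_gained", "start_lost",
}
RETAINED_LABELS = LOF_LABELS | {"missense", "inframe_indel", "splice_region"}


def oracle_passes(
    consequence_label: str,
    predictor_verdicts: list[str],
    frequencies: dict[str, float],
    site_quality,
    read_depth,
    mapping_quality,
    *,
    maf_threshold: float,
    maf_inclusive: bool,
    vote_mode: str,
    quality_gate_enabled: bool = True,
    min_site_quality: float = 30.0,
    min_depth: int = 20,
    min_mapping_quality: float = 45.0,
    primary_population: str = "NFE",
    fallback_population: str = "EUR_1KG",
) -> bool:
    """True iff the variant survives the whole cascade, from first principles."""
    # stage 1: call quality
    if quality_gate_enabled:
        if site_quality is None or read_depth is None or mapping_quality is None:
            return False
        if site_quality < min_site_quality:
            return False
        if read_depth < min_depth:
            return False
        if mapping_quality < min_mapping_quality:
            return False

    # stage 2: rarity, primary population first, fallback second, novel = 0
    if primary_population in frequencies:
        maf = frequencies[primary_population]
    elif fallback_population in frequencies:
        maf = frequencies[fallback_population]
    else:
        maf = 0.0
    if maf_inclusive:
        if maf > maf_threshold:
            return False
    else:
        if maf >= maf_threshold:
            return False

    # stage 3: consequence severity
    if consequence_label not in RETAINED_LABELS:
        return False

    # stage 4: pathogenicity tier
    is_lof = consequence_label in LOF_LABELS
    informative = [v for v in predictor_verdicts if v != "unknown"]
    n_del = sum(1 for v in informative if v == "deleterious")
    if vote_mode == "lof_only":
        return is_lof
    if vote_mode == "all":
        return is_lof or (len(informative) > 0 and n_del == len(informative))
    if vote_mode == "majority":
        return is_lof or (len(informative) > 0 and n_del > len(informative) / 2)
    raise ValueError(vote_mode)


ALL_LABELS = sorted(RETAINED_LABELS) + [
    "synonymous", "intronic", "intergenic", "other", "unknown",
]
VERDICTS = ["deleterious", "benign", "unknown"]


def random_variant_spec(rng: np.random.Generator) -> dict:
    """Random raw variant attributes, biased toward boundary values."""
    label = ALL_LABELS[rng.integers(0, len(ALL_LABELS))]
    n_calls = int(rng.integers(0, 7))
    verdicts = [VERDICTS[rng.integers(0, 3)] for _ in range(n_calls)]

    def draw_maf():
        r = rng.random()
        if r < 0.25:  # exactly at a tier threshold
            return float(rng.choice([0.10, 0.01, 0.005, 0.0005]))
        return round(float(np.exp(rng.uniform(np.log(1e-6), np.log(0.9)))), 8)

    frequencies = {}
    for pop in ("NFE", "EUR_1KG", "AFR"):
        if rng.random() < 0.6:
            frequencies[pop] = draw_maf()

    def draw_metric(threshold, spread):
        r = rng.random()
        if r < 0.1:
            return None
        if r < 0.3:
            return float(threshold)  # exactly at the gate
        return float(threshold + rng.uniform(-spread, spread))

    return {
        "consequence_label": label,
        "predictor_verdicts": verdicts,
        "frequencies": frequencies,
        "site_quality": draw_metric(30.0, 25.0),
        "read_depth": (lambda m: None if m is None else int(round(m)))(
            draw_metric(20.0, 15.0)),
        "mapping_quality": draw_metric(45.0, 20.0),
    }
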