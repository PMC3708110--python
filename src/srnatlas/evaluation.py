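"""Score a pipeline run against the synthetic generator's planted truth.

Used by the test suite and the reproducibility script to turn a
:class:`~srnatlas.pipeline.RunResult` plus the generating
:class:`~srnatlas.synthetic.Manifest` into recovery metrics: novel-hairpin
sensitivity, decoy pass rate, planted-miRNA detection, and recovered
isomiR/star/editing/class statistics.
"""

from __future__ import annotations

from .isomir import arm_ratio, variant_profile
from .pipeline import RunResult
from .synthetic import Manifest

__all__ = [
    "novel_discovery_metrics",
    "mirna_recovery_metrics",
    "isomir_recovery",
]


def _loci(items: list[dict]) -> dict[str, tuple[str, int, int]]:
    out = {}
    for it in items:
        for fid, (chrom, s, e) in it.get("loci", {}).items():
            out[it["name"]] = (chrom, s, e)
    return out


def _hits_locus(candidate, locus: tuple[str, int, int]) -> bool:
    iv = candidate.interval
    chrom, s, e = locus
    return iv.chrom == chrom and iv.start < e and iv.end > s


def novel_discovery_metrics(manifest: Manifest, result: RunResult) -> dict:
    """Sensitivity over planted novel hairpins and decoy pass rate."""
    passed = [c for c in result.candidates if c.passed]
    novels = _loci(manifest.novels)
    decoys = _loci(manifest.decoys)
    recovered = {
        name for name, locus in novels.items() if any(_hits_locus(c, locus) for c in passed)
    }
    decoy_passes = {
        name for name, locus in decoys.items() if any(_hits_locus(c, locus) for c in passed)
    }
    other = [
        c
        for c in passed
        if not any(_hits_locus(c, l) for l in novels.values())
        and not any(_hits_locus(c, l) for l in decoys.values())
    ]
    return {
        "n_planted": len(novels),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(novels) if novels else 0.0,
        "n_decoys": len(decoys),
        "n_decoy_passes": len(decoy_passes),
        "decoy_pass_rate": len(decoy_passes) / len(decoys) if decoys else 0.0,
        "n_other_passes": len(other),
    }


def mirna_recovery_metrics(manifest: Manifest, result: RunResult, min_count: int = 3) -> dict:
    """Detection and ranking of the planted miRNA population."""
    counts = {r.name: r.total_reads for r in result.expression}
    detected = [m["name"] for m in manifest.mirnas if counts.get(m["name"], 0) >= min_count]
    heaviest = max(manifest.mirnas, key=lambda m: m["weight"])["name"]
    top_frac = None
    total = sum(counts.values())
    if total and result.expression:
        top_frac = result.expression[0].total_reads / total
    return {
        "n_planted": len(manifest.mirnas),
        "n_detected": len(detected),
        "all_detected": len(detected) == len(manifest.mirnas),
        "heaviest_ranked_first": bool(result.expression) and result.expression[0].name == heaviest,
        "heaviest_name": heaviest,
        "top_mirna_fraction": top_frac,
    }


def isomir_recovery(manifest: Manifest, result: RunResult, mirna_index: int) -> dict:
    """Recovered offset distribution, star fraction and A-to-G profile."""
    m = manifest.mirnas[mirna_index]
    prof = result.profiles.get(m["name"])
    out: dict = {"name": m["name"], "planted": m["isomir_dist"]}
    if prof is None:
        return {**out, "offsets": {}, "star_fraction": None, "a_to_g": {}}
    total = sum(r.count for r in prof.isomirs if r.arm == "mature")
    offsets = {}
    for r in prof.isomirs:
        if r.arm != "mature":
            continue
        key = f"{r.offset5},{r.offset3}"
        offsets[key] = offsets.get(key, 0) + r.count
    out["offsets"] = {k: v / total for k, v in offsets.items()} if total else {}
    out["offset_counts"] = offsets
    out["star_fraction"] = arm_ratio(prof)
    _, a_to_g = variant_profile(prof.isomirs, m["mature"])
    out["a_to_g"] = a_to_g
    return out
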