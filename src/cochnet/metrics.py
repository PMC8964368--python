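"""Recovery metrics against a generator's ground truth."""

from __future__ import annotations

from sklearn.metrics import adjusted_rand_score

from .network import ModulePartition, UNASSIGNED
from .simulate import GroundTruth


def module_recovery_ari(truth: GroundTruth, part: ModulePartition,
                        signal_only: bool = True) -> float:
    """Adjusted Rand index between planted and recovered module labels.

    Scored over the planted genes present in the partition; with
    ``signal_only`` (default) null-profile modules are excluded — their
    genes carry no correlation signal by construction, so they are not a
    recovery target.
    """
    modules = truth.signal_modules() if signal_only else list(
        truth.module_profiles
    )
    keep = set(modules)
    genes = [
        g for g, m in truth.gene_module.items()
        if m in keep and g in part.labels.index
    ]
    if not genes:
        return 0.0
    planted = [truth.gene_module[g] for g in genes]
    recovered = [part.labels[g] for g in genes]
    return float(adjusted_rand_score(planted, recovered))


def match_modules(truth: GroundTruth, part: ModulePartition,
                  signal_only: bool = True) -> dict[str, str | None]:
    """Best-overlap map planted module -> recovered label (Jaccard argmax).

    A planted module maps to ``None`` when its best match is the unassigned
    label or shares no genes with any recovered module.
    """
    modules = truth.signal_modules() if signal_only else list(
        truth.module_profiles
    )
    out: dict[str, str | None] = {}
    recovered_members = {
        lab: set(part.members(lab)) for lab in part.modules()
    }
    for m in modules:
        planted = {g for g in truth.module_members(m) if g in part.labels.index}
        best, best_j = None, 0.0
        for lab, mem in recovered_members.items():
            inter = len(planted & mem)
            if inter == 0:
                continue
            j = inter / len(planted | mem)
            if j > best_j:
                best, best_j = lab, j
        out[m] = best if best != UNASSIGNED else None
    return out
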