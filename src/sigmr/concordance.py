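"""Perturbed-gene calling and directional overlap between compound pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import ExpressionSignature


@dataclass(frozen=True)
class PerturbedGeneSets:
    """Genes up-/down-regulated past a strict z threshold."""

    up: frozenset
    down: frozenset
    threshold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down perturbed sets overlap")

    @property
    def all(self) -> frozenset:
        return self.up | self.down


@dataclass(frozen=True)
class SharedPerturbation:
    """Same-/opposite-direction overlap of two compounds' perturbed genes."""

    same_direction: frozenset
    opposite_direction: frozenset
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.same_direction & self.opposite_direction:
            raise ValueError("same and opposite sets overlap")


def perturbed_genes(sig: ExpressionSignature, threshold: float = 1.0) -> PerturbedGeneSets:
    """Genes with z strictly above the threshold (up) or below its negative (down).

    A gene at exactly +/-threshold is excluded (strict inequalities).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = np.asarray(sig.z)
    up = frozenset(g for g, v in zip(sig.gene_ids, z) if v > threshold)
    down = frozenset(g for g, v in zip(sig.gene_ids, z) if v < -threshold)
    return PerturbedGeneSets(up=up, down=down, threshold=threshold)


def shared_perturbation(
    sig_a: ExpressionSignature,
    sig_b: ExpressionSignature,
    threshold: float = 1.0,
) -> SharedPerturbation:
    """Genes perturbed by both compounds, split by direction agreement."""
    pa = perturbed_genes(sig_a, threshold)
    pb = perturbed_genes(sig_b, threshold)
    same = (pa.up & pb.up) | (pa.down & pb.down)
    opposite = (pa.up & pb.down) | (pa.down & pb.up)
    pair = (
        str(sig_a.meta.get("column_id", "a")),
        str(sig_b.meta.get("column_id", "b")),
    )
    return SharedPerturbation(same_direction=same, opposite_direction=opposite, pair=pair)


def shared_perturbation_frame(
    sig_a: ExpressionSignature,
    sig_b: ExpressionSignature,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Long-format report: gene, z in each signature, direction class."""
    shared = shared_perturbation(sig_a, sig_b, threshold)
    za = sig_a.as_series()
    zb = sig_b.as_series()
    rows = []
    for g in sorted(shared.same_direction | shared.opposite_direction):
        if g in shared.opposite_direction:
            cls = "opposite"
        elif za[g] > threshold:
            cls = "same_up"
        else:
            cls = "same_down"
        rows.append({"gene": g, "z_a": float(za[g]), "z_b": float(zb[g]), "direction_class": cls})
    return pd.DataFrame(rows, columns=["gene", "z_a", "z_b", "direction_class"])
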