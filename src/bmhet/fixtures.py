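"""Synthetic dataset bundles shaped like the package's motivating analyses.

Three kinds are provided:

* ``two-regime-clade`` — a derived regime painted on one clade with the
  shift at the midpoint of its stem branch (the classic two-regime
  clade-contrast design); traits simulated under the no-common-structure
  model by default.
* ``three-regime-mk`` — a three-state regime history evolved under an
  equal-rates Mk process and accepted only when every state reaches a
  minimum tip count; traits simulated under a chosen generating model
  (default: varying rate for trait 1 and varying correlation).
* ``single-regime`` — one regime everywhere; traits under the common
  rates / common correlation model.

Each bundle is a painted tree (simmap), a trait table (CSV) and a
``truth.json`` recording the generating model, parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelSpec, RateMatrix
from .simulate import (
    draw_generating_params,
    sim_mvbm,
    sim_pure_birth,
    sim_regime_history,
)
from .trees import PaintedTree, paint_clade, paint_uniform, write_simmap

__all__ = ["FixtureBundle", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("two-regime-clade", "three-regime-mk", "single-regime")


@dataclass
class FixtureBundle:
    tree: PaintedTree
    traits: pd.DataFrame
    spec: ModelSpec
    rates: dict[str, RateMatrix]
    seed: int
    kind: str

    def truth(self) -> dict:
        return {
            "kind": self.kind,
            "model": self.spec.code,
            "regimes": list(self.spec.regimes),
            "rates": {
                g: {"sigma2_1": R.sigma2_1, "sigma2_2": R.sigma2_2, "r": R.r}
                for g, R in self.rates.items()
            },
            "roots": [0.0, 0.0],
            "seed": self.seed,
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.simmap").write_text(write_simmap(self.tree) + "\n")
        self.traits.rename_axis("taxon").to_csv(out / "traits.csv")
        (out / "truth.json").write_text(json.dumps(self.truth(), indent=1) + "\n")
        return out


def _clade_of_size(tree, lo: int, hi: int):
    """A non-root node whose subtree holds between lo and hi tips."""
    sizes = {}
    for node in tree.postorder():
        sizes[node] = 1 if node.is_tip else sum(sizes[c] for c in node.children)
    best = None
    for node in tree.edges():
        if lo <= sizes[node] <= hi:
            if best is None or sizes[node] > sizes[best]:
                best = node
    if best is None:  # fall back to the largest non-root clade below hi
        cands = [n for n in tree.edges() if sizes[n] <= hi]
        best = max(cands, key=lambda n: sizes[n])
    return best


def make_fixture(
    kind: str,
    seed: int = 0,
    n_taxa: int | None = None,
    model: str | None = None,
) -> FixtureBundle:
    """Build a synthetic dataset bundle of the given kind, fully seeded."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "two-regime-clade":
        n = n_taxa or 40
        code = model or "4"
        tree = sim_pure_birth(n, seed=rng)
        node = _clade_of_size(tree, n // 4, n // 2)
        painted = paint_clade(tree, node, regime="derived", base_regime="base",
                              shift_fraction=0.5)
    elif kind == "three-regime-mk":
        n = n_taxa or 100
        code = model or "3b"
        min_tips = max(2, n // 5)
        tree = sim_pure_birth(n, seed=rng)
        painted = sim_regime_history(tree, 3, rate=2.0 / tree.height,
                                     min_tips=min_tips, seed=rng)
    else:  # single-regime
        n = n_taxa or 50
        code = model or "1"
        tree = sim_pure_birth(n, seed=rng)
        painted = paint_uniform(tree, "0")
    spec = ModelSpec(code, tuple(painted.regimes))
    rates = draw_generating_params(spec, rng)
    traits = sim_mvbm(painted, rates, seed=rng)
    return FixtureBundle(painted, traits, spec, rates, seed, kind)
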