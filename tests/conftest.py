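import numpy as np
import pytest

from mircotrain import (
    HairpinCandidate,
    Interval,
    ReadStack,
    RegionAnnotation,
    SequenceRecord,
    SplitSpec,
    TwoViewSimConfig,
    ViewState,
    gen_two_view,
    make_forest_factory,
    split_and_seed,
)

RNG_SEED = 20240117


@pytest.fixture
def rng():
    return np.random.default_rng(RNG_SEED)


@pytest.fixture
def toy_hairpin():
    """Perfect 12-bp stem around a 6-nt loop with annotated regions.

    mature = [0, 12) on the 5' arm; its partners are [18, 30), so with the
    2-nt overhang star = [20, 30) and the loop spans [12, 20).
    """
    seq = "G" * 12 + "A" * 6 + "C" * 12
    structure = "(" * 12 + "." * 6 + ")" * 12
    regions = RegionAnnotation(
        mature=Interval(0, 12),
        star=Interval(20, 30),
        loop=Interval(12, 20),
        lower_stem_limit=0,
    )
    def build(stacks, library_size=1_000_000, with_regions=True):
        return HairpinCandidate(
            record=SequenceRecord(id="toy", residues=seq),
            structure=structure,
            stacks=list(stacks),
            regions=regions if with_regions else None,
            library_size=library_size,
        )
    return build


@pytest.fixture
def small_two_view():
    """A small, well-separated two-view dataset plus aligned splits."""
    cfg = TwoViewSimConfig(
        n_pos=40, n_neg=40, dims_a=3, dims_b=3, sep_a=3.0, sep_b=3.0,
        noise_dims_a=2, noise_dims_b=2, rng_seed=RNG_SEED,
    )
    view_a, view_b, labels = gen_two_view(cfg)
    spec = SplitSpec(rng_seed=RNG_SEED)
    seed_a, pool_a, hold_a = split_and_seed(view_a, spec)
    seed_b, pool_b, hold_b = split_and_seed(view_b, spec)
    return {
        "views": (view_a, view_b),
        "states": lambda: (
            ViewState("seq", seed_a.subset(seed_a.instance_ids), pool_a.subset(pool_a.instance_ids)),
            ViewState("expr", seed_b.subset(seed_b.instance_ids), pool_b.subset(pool_b.instance_ids)),
        ),
        "holdout": (hold_a, hold_b),
    }


@pytest.fixture
def fast_factory():
    """Small forest for bookkeeping-level tests (the contract, not the power)."""
    return make_forest_factory(25)
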