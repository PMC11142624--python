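import numpy as np
import pytest

from splicescope import (
    ASEvent,
    FixtureSpec,
    build_db,
    simulate_annotation,
    simulate_das_outputs,
    simulate_feature_tracks,
)
from splicescope.events import COORD_ARITY, EVENT_TYPES


def random_event(rng: np.random.Generator, event_type: str = None) -> ASEvent:
    """A random valid event; coordinate gaps >= 25 bp so no geometry is
    degenerate and w=10 boundary windows stay on-contig."""
    etype = event_type or str(rng.choice(EVENT_TYPES))
    arity = COORD_ARITY[etype]
    start = int(rng.integers(100, 5_000))
    gaps = rng.integers(25, 400, size=arity - 1)
    coords = [start]
    for g in gaps:
        coords.append(coords[-1] + int(g))
    strand = "+" if rng.random() < 0.5 else "-"
    return ASEvent(
        gene=f"G{int(rng.integers(0, 10_000))}",
        event_type=etype,
        chrom=f"chr{int(rng.integers(1, 5))}",
        strand=strand,
        coords=tuple(coords),
    )


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11, n_genes=30)


@pytest.fixture(scope="session")
def sim_bundle(spec, tmp_path_factory):
    """One fully materialised fixture study shared by the suite."""
    root = tmp_path_factory.mktemp("fixture")
    gtf_text, truth, ann = simulate_annotation(spec)
    das_paths = simulate_das_outputs(truth, spec, str(root / "das"))
    track_paths, ledger = simulate_feature_tracks(truth, spec, ann, str(root / "tracks"))
    gtf_path = root / "annotation.gtf"
    gtf_path.write_text(gtf_text)
    db = build_db(ann, track_paths, str(root / "features.sqlite"))
    return {
        "spec": spec,
        "gtf_text": gtf_text,
        "gtf_path": str(gtf_path),
        "truth": truth,
        "annotation": ann,
        "das": das_paths,
        "tracks": track_paths,
        "ledger": ledger,
        "db": db,
    }
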