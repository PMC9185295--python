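"""Shared fixtures: the default synthetic study dataset, generated in memory."""

import pytest

from ofpcanet import SynthSpec, make_synthetic_clips
from ofpcanet.clip_io import DatasetIndex, ManifestEntry


@pytest.fixture(scope="session")
def default_synthetic_dataset():
    """The default study conditions: 6 subjects x 3 classes x 3 clips,
    64x64 frames, 2 px/frame peak motion, sigma 0.01 intensity noise,
    fixed seed.  Returns (clips dict, index, ground-truth fields)."""
    spec = SynthSpec()  # defaults ARE the study conditions
    triples = make_synthetic_clips(spec)
    clips = {c.clip_id: c for c, _, _ in triples}
    gt = {c.clip_id: (du, dv) for c, du, dv in triples}
    index = DatasetIndex(
        entries=[
            ManifestEntry(c.clip_id, "", c.subject_id, c.label)
            for c, _, _ in triples
        ]
    )
    return clips, index, gt
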