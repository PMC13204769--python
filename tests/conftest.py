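import numpy as np
import pytest
from hypothesis import settings

import neglectscore as ns
from neglectscore.config import DEFAULT_CONFIG

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def templates():
    return ns.make_template_set()


@pytest.fixture(scope="session")
def sv_tables(templates):
    from neglectscore.report import default_sv_tables
    return default_sv_tables(templates)


def pipeline_run(subtest, spec_kwargs, templates, sv_tables,
                 config=DEFAULT_CONFIG):
    """Render a synthetic sheet and run the full scoring pipeline on it."""
    spec = ns.SyntheticSpec(subtest_id=subtest, **spec_kwargs)
    sheet, truth = ns.render_sheet(spec, config)
    template = templates[subtest]
    norm = ns.normalize_sheet(sheet.pixels, template, config)
    ink = ns.extract_ink(norm, template, config)
    score = ns.score_sheet_image(norm, template, sv_tables, config)
    return truth, norm, ink, score


@pytest.fixture(scope="session")
def run_pipeline(templates, sv_tables):
    def _run(subtest, **spec_kwargs):
        return pipeline_run(subtest, spec_kwargs, templates, sv_tables)
    return _run


def make_ink_mask(mask: np.ndarray) -> ns.InkMask:
    """Wrap a raw boolean grid as an InkMask for scorer-level tests."""
    return ns.InkMask(mask=mask.astype(bool), threshold=128.0,
                      strict_count=int(mask.sum()),
                      loose_count=int(mask.sum()), speck_count=0,
                      faint_ratio=0.0)
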