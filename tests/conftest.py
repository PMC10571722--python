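import json

import numpy as np
import pandas as pd
import pytest

from cellfusion.nuclei_io import BlockSpec, NucleiTable


@pytest.fixture
def toy_table():
    """Small mapped nuclei table on a 256x256 slide (window centers known)."""
    records = pd.DataFrame(
        {
            "centroid_x": [10.0, 70.0, 10.0, 200.0, 130.0],
            "centroid_y": [10.0, 10.0, 70.0, 200.0, 130.0],
            "raw_class": ["neoplastic", "neoplastic", "inflammatory", "connective", "dead"],
            "merged_class": ["neoplastic", "neoplastic", "inflammatory", "miscellaneous", "miscellaneous"],
        }
    )
    return NucleiTable(records=records, slide_width=256, slide_height=256)


def write_block_json(path, nuclei):
    """nuclei: list of (x, y, type_id) in block-local coordinates."""
    payload = {
        str(i): {"centroid": [float(x), float(y)], "type": int(t)}
        for i, (x, y, t) in enumerate(nuclei)
    }
    path.write_text(json.dumps(payload))
    return path


@pytest.fixture
def block_json_factory(tmp_path):
    def factory(name, nuclei):
        return write_block_json(tmp_path / name, nuclei)

    return factory
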