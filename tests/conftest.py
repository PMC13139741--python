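import pytest

import kanokit as kk

# Published quadrant memberships for the bundled 26-item nurse-demand survey.
EXPECTED_MEMBERSHIP = {
    "I": ["2", "3", "4", "11", "15", "16", "19", "20"],
    "II": ["1", "9", "12", "13", "14", "24", "26"],
    "III": ["17", "22", "23"],
    "IV": ["5", "6", "7", "8", "10", "18", "21", "25"],
}

# Printed per-item (attribute, DSI, SI) at 2 dp, keyed by item id.
EXPECTED_TABLE = {
    "1": ("A", -0.33, 0.61),
    "2": ("O", -0.58, 0.59),
    "3": ("O", -0.56, 0.55),
    "4": ("O", -0.47, 0.57),
    "5": ("M", -0.56, 0.44),
    "6": ("M", -0.56, 0.34),
    "7": ("M", -0.62, 0.36),
    "8": ("M", -0.51, 0.39),
    "9": ("A", -0.23, 0.51),
    "10": ("M", -0.60, 0.42),
    "11": ("O", -0.53, 0.58),
    "12": ("A", -0.23, 0.55),
    "13": ("A", -0.29, 0.55),
    "14": ("A", -0.15, 0.52),
    "15": ("O", -0.52, 0.50),
    "16": ("O", -0.43, 0.62),
    "17": ("I", -0.22, 0.39),
    "18": ("M", -0.61, 0.39),
    "19": ("O", -0.61, 0.57),
    "20": ("O", -0.46, 0.61),
    "21": ("M", -0.52, 0.36),
    "22": ("I", -0.28, 0.41),
    "23": ("I", -0.33, 0.39),
    "24": ("A", -0.29, 0.58),
    "25": ("M", -0.47, 0.43),
    "26": ("A", -0.18, 0.49),
}


@pytest.fixture(scope="session")
def nurse_freqs():
    return kk.load_nurse_demand()


@pytest.fixture(scope="session")
def nurse_report(nurse_freqs):
    return kk.run_pipeline(nurse_freqs)
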