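"""Scalp regions of the 21-channel 10-20 montage.

Channels are clustered into anterior, central, and posterior groups for
regional aggregation of complexity scores, and the central cluster doubles
as the target of the lesion transform.

The montage carries 21 electrodes including the anterior-temporal pair
T1/T2, which the three clusters proper do not cover; the default map files
T1 and T2 under ``anterior`` (their nearest cluster) so that every channel
contributes to exactly one region.
"""

from __future__ import annotations

REGIONS = ("anterior", "central", "posterior")

#: Full 21-electrode montage, in recording order.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "T1", "T2", "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

#: The three scalp clusters used for regional summaries.
ANTERIOR_CHANNELS = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"]
CENTRAL_CHANNELS = ["T3", "C3", "Cz", "C4", "T4"]
POSTERIOR_CHANNELS = ["T5", "P3", "Pz", "P4", "T6", "O1", "O2"]


def default_region_map() -> dict[str, str]:
    """Map every default channel to its region.

    T1 and T2 are assigned to ``anterior``; the lesion target set
    (:data:`CENTRAL_CHANNELS`) is unaffected by this choice.
    """
    mapping: dict[str, str] = {}
    for ch in ANTERIOR_CHANNELS + ["T1", "T2"]:
        mapping[ch] = "anterior"
    for ch in CENTRAL_CHANNELS:
        mapping[ch] = "central"
    for ch in POSTERIOR_CHANNELS:
        mapping[ch] = "posterior"
    return mapping


def validate_region_map(mapping: dict[str, str]) -> None:
    """Check that every value is a known region name."""
    bad = {r for r in mapping.values() if r not in REGIONS}
    if bad:
        raise ValueError(f"unknown region names {sorted(bad)}; expected one of {REGIONS}")
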