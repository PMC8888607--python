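"""Bundled reference tables.

``GORILLA_SHOULDER`` holds the published evaluation data for five western
lowland gorilla shoulder muscles: dissection-based measured masses (kg) and
the volumes (cm³) of the corresponding volumetric 3D muscle models.  It is
the standard worked example for the volume→mass layer: running the modelled
volumes through :func:`myoline.mass.mass_from_volume` at 1060 kg/m³
reproduces the modelled masses, and comparing summed modelled against
summed measured mass quantifies the overall underestimation of the
modelling approach (≈2.7% from these printed inputs).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["GORILLA_SHOULDER", "gorilla_shoulder_table"]

#: muscle name -> (measured dissection mass [kg], modelled volume [cm³])
GORILLA_SHOULDER = {
    "M. deltoideus clavicularis": (0.063, 65.405),
    "M. deltoideus acromialis": (0.166, 140.047),
    "M. deltoideus spinalis": (0.057, 51.387),
    "M. supraspinatus": (0.084, 79.440),
    "M. infraspinatus": (0.105, 99.730),
}


def gorilla_shoulder_table() -> pd.DataFrame:
    """The gorilla shoulder evaluation data as a DataFrame."""
    return pd.DataFrame(
        [
            {"muscle": k, "measured_mass_kg": m, "modelled_volume_cm3": v}
            for k, (m, v) in GORILLA_SHOULDER.items()
        ]
    )
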