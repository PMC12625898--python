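"""Embedded study tables for the Starosele multi-proxy analysis.

Everything here is small enough to live as literals: the dated-specimen
table behind the primary habitat suitability model, the three region
boxes, the published collagen peptide-marker masses for Hominidae together
with a synthetic reference library for the faunal taxa, the observed
Star 1 (Z00113) MALDI peak list, the per-square bone counts, and the two
radiocarbon determinations on the Star 1 bone.

The faunal (non-Hominidae) marker masses are SYNTHETIC: plausible
monoisotopic [M+H]+ values with realistic spacing, constructed so each
taxon is uniquely identifiable at the default +/-0.2 Da tolerance while a
few peptides are deliberately shared between related clades. Only the six
Hominidae masses are observed values.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "starosele_occurrences",
    "region_boxes",
    "reference_markers",
    "star1_peaks",
    "bone_counts",
    "radiocarbon_dates",
]

# Dated specimens with age uncertainty used by the primary niche model.
# Ages are in calendar years BP; the first age column holds the older bound
# as printed (see niche.load_occurrences for normalization).
_OCCURRENCES_CSV = """\
specimen,latitude,longitude,min_age,max_age,location,method
Vi-33-19,46.301562,16.079687,50901,45561,Box 1,Age at 68.3% probability
Vi-208,46.301562,16.079687,47256,44126,Box 1,Age at 68.3% probability
Vi-207,46.301562,16.079687,48904,44579,Box 1,Age at 68.3% probability
Mammoth layer D OxA-24944,50.366,19.294,52257,46646,Box 1,Age at 68.3% probability
Star 1,44.75,33.92,43858,42695,Box 2,Age at 68.3% probability
Mezmaiskaya 2,44.5540,39.5534,43986,42526,Box 2,Age at 68.3% probability
Chagyrskaya Level 6a,51.263299,83.091628,53000,48200,Box 4,Weighted arithmetic mean age from four samples
Chagyrskaya Level 6b,51.263299,83.091628,55000,49200,Box 4,Weighted arithmetic mean age from two samples
Chagyrskaya Level 6C,51.263299,83.091628,57400,52400,Box 4,Weighted arithmetic mean age from nine samples
Layer 7 sediment a,51.40,84.20,51338,44716,Box 4,Age at 68.3% probability
Layer 7 sediment b,51.40,84.20,51903,44801,Box 4,Age at 68.3% probability
Denisova 11,51.235,84.403,118100,79300,Box 4,
"""

# Region boxes (label, lon_min, lon_max, lat_min, lat_max), degrees E / N.
_BOXES = {
    "Box 1": ("Croatia/Poland", 12.5, 21.0, 44.0, 53.0),
    "Box 2": ("Crimean Peninsula", 31.0, 43.5, 43.5, 49.0),
    "Box 4": ("Altai region", 80.0, 89.0, 47.5, 53.0),
}

# Collagen peptide-marker reference library, monoisotopic [M+H]+ in Da.
# Hominidae rows: observed masses for markers A-D, F, G; marker E is not
# reliably recovered from degraded human collagen and is left absent.
# All other taxa: synthetic masses (see module docstring).
_MARKERS_CSV = """\
taxon,marker,mz
Hominidae,A,1235.71
Hominidae,B,1478.74
Hominidae,C,1580.86
Hominidae,D,2115.19
Hominidae,F,2869.56
Hominidae,G,2957.68
Equus,A,1105.60
Equus,B,1427.75
Equus,C,1550.84
Equus,D,2129.10
Equus,E,2187.15
Equus,F,2853.55
Equus,G,2899.60
Bovidae,A,1192.70
Bovidae,B,1427.75
Bovidae,C,1648.95
Bovidae,D,2131.20
Bovidae,E,2792.40
Bovidae,F,2883.60
Bovidae,G,3017.30
Cervidae,A,1180.65
Cervidae,B,1439.80
Cervidae,C,1648.95
Cervidae,D,2131.20
Cervidae,E,2808.45
Cervidae,F,2871.60
Cervidae,G,3033.35
Rhinocerotidae,A,1141.60
Rhinocerotidae,B,1453.80
Rhinocerotidae,C,1566.85
Rhinocerotidae,D,2139.10
Rhinocerotidae,E,2219.20
Rhinocerotidae,F,2901.65
Rhinocerotidae,G,3059.40
Canis lupus,A,1123.60
Canis lupus,B,1465.85
Canis lupus,C,1594.88
Canis lupus,D,2147.15
Canis lupus,E,2247.25
Canis lupus,F,2917.70
Canis lupus,G,3077.45
Saiga,A,1166.65
Saiga,B,1443.80
Saiga,C,1634.92
Saiga,D,2163.18
Saiga,E,2275.28
Saiga,F,2931.72
Saiga,G,3093.50
"""

# Observed m/z peaks in the Star 1 (Z00113) MALDI spectrum that carry the
# Hominidae peptide markers A-D, F, G; marker E was absent.
_STAR1_PEAKS = (1235.71, 1478.74, 1580.86, 2115.19, 2869.56, 2957.68)

# Bones analyzed for collagen fingerprinting, per excavation square.
_BONE_COUNTS = (
    ("Starosele-Level-3-Industry", 3, "F21", 20),
    ("Micoquian", 1, "G21", 20),
    ("Micoquian", 1, "H23", 20),
    ("Micoquian", 1, "I23", 70),
    ("Micoquian", 1, "I22", 20),
)

# Radiocarbon determinations on the Star 1 bone (14C yr BP, 1 sigma).
_RC_DATES = (
    ("VIE-1203", 39858, 736, "ultrafiltration"),
    ("VIE-1541", 43212, 295, "XAD-2 amino acids"),
)


def starosele_occurrences() -> pd.DataFrame:
    """Dated-specimen table for the primary habitat suitability model.

    Returns the 12 records with columns ``specimen, latitude, longitude,
    min_age, max_age, location, method``; ages in calendar years BP, exactly
    as printed (use :func:`paleotrail.niche.load_occurrences` to normalize
    the age bounds to (older, younger)).
    """
    return pd.read_csv(io.StringIO(_OCCURRENCES_CSV))


def region_boxes():
    """The three sampling-region boxes as a dict label -> RegionBox."""
    from .niche import RegionBox

    return {
        key: RegionBox(key, lon_min, lon_max, lat_min, lat_max, name=name)
        for key, (name, lon_min, lon_max, lat_min, lat_max) in _BOXES.items()
    }


def reference_markers():
    """Peptide-marker reference library as a :class:`~paleotrail.zooms.MarkerTable`."""
    from .zooms import MarkerTable

    return MarkerTable.from_frame(pd.read_csv(io.StringIO(_MARKERS_CSV)))


def star1_peaks():
    """Observed Star 1 marker peaks as a :class:`~paleotrail.zooms.PeakList`."""
    from .zooms import PeakList

    return PeakList.from_mz(_STAR1_PEAKS)


def bone_counts() -> pd.DataFrame:
    """Bones analyzed per excavation square (typology, level, square, n_bones)."""
    return pd.DataFrame(
        _BONE_COUNTS, columns=["typology", "level", "square", "n_bones"]
    )


def radiocarbon_dates():
    """The two determinations on the Star 1 bone as RadiocarbonDate objects."""
    from .calibration import RadiocarbonDate

    return {
        lab: RadiocarbonDate(age=age, sigma=sigma, lab_code=lab, pretreatment=prep)
        for lab, age, sigma, prep in _RC_DATES
    }
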