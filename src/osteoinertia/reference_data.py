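"""Published reference statistics for adult metatarsal bones.

Per-sex summary statistics (mean, SD, min, max) of the eight normalized
geometric and inertial variables for the five metatarsals of both feet,
measured on a cohort of 60 young adult Chinese volunteers (30 male,
30 female), together with the ten published sex-discriminant functions
derived from those data by stepwise discriminant function analysis.

Variable naming follows the cohort CSV schema used throughout the package:

========  ====================================================
column    meaning
========  ====================================================
Ln        normalized bone length  Lp / (Lp + Wp + Hp)
Wn        normalized bone width   Wp / (Lp + Wp + Hp)
Hn        normalized bone height  Hp / (Lp + Wp + Hp)
sa_v      surface-area-to-volume ratio S / V  [1/mm]
density   mean voxel gray value / 1024 (water == 1024)
pmi_x     normalized principal moment of inertia, x (plantar-dorsal)
pmi_y     normalized principal moment of inertia, y (medial-lateral)
pmi_z     normalized principal moment of inertia, z (long axis)
========  ====================================================

Normalized triplets are stored as fractions summing to 1 (an optional
percent display is applied only at output time).
"""

from __future__ import annotations

from typing import NamedTuple

VARIABLES: tuple[str, ...] = (
    "Ln", "Wn", "Hn", "sa_v", "density", "pmi_x", "pmi_y", "pmi_z",
)

SIDES: tuple[str, str] = ("left", "right")
METATARSALS: tuple[int, ...] = (1, 2, 3, 4, 5)
SEXES: tuple[str, str] = ("male", "female")


class SummaryStat(NamedTuple):
    """Per-sex summary of one variable: mean, SD and observed range."""

    mean: float
    sd: float
    min: float
    max: float


def _s(mean, sd, lo, hi) -> SummaryStat:
    return SummaryStat(mean, sd, lo, hi)


#: (side, metatarsal) -> variable -> sex -> SummaryStat
COHORT_STATS: dict[tuple[str, int], dict[str, dict[str, SummaryStat]]] = {
    ("left", 1): {
        "Ln": {"male": _s(0.553, 0.014, 0.528, 0.577), "female": _s(0.563, 0.011, 0.543, 0.586)},
        "Wn": {"male": _s(0.251, 0.008, 0.225, 0.265), "female": _s(0.247, 0.006, 0.238, 0.265)},
        "Hn": {"male": _s(0.196, 0.008, 0.182, 0.214), "female": _s(0.190, 0.009, 0.174, 0.210)},
        "sa_v": {"male": _s(0.256, 0.016, 0.224, 0.297), "female": _s(0.289, 0.014, 0.262, 0.315)},
        "density": {"male": _s(1.602, 0.059, 1.452, 1.718), "female": _s(1.577, 0.054, 1.436, 1.670)},
        "pmi_x": {"male": _s(0.462, 0.005, 0.446, 0.470), "female": _s(0.466, 0.003, 0.460, 0.471)},
        "pmi_y": {"male": _s(0.452, 0.005, 0.444, 0.467), "female": _s(0.457, 0.004, 0.449, 0.467)},
        "pmi_z": {"male": _s(0.087, 0.009, 0.064, 0.099), "female": _s(0.078, 0.006, 0.063, 0.089)},
    },
    ("right", 1): {
        "Ln": {"male": _s(0.550, 0.013, 0.525, 0.574), "female": _s(0.563, 0.011, 0.542, 0.583)},
        "Wn": {"male": _s(0.253, 0.008, 0.224, 0.269), "female": _s(0.246, 0.005, 0.233, 0.255)},
        "Hn": {"male": _s(0.197, 0.008, 0.182, 0.215), "female": _s(0.191, 0.008, 0.174, 0.202)},
        "sa_v": {"male": _s(0.256, 0.016, 0.223, 0.299), "female": _s(0.290, 0.013, 0.263, 0.315)},
        "density": {"male": _s(1.605, 0.072, 1.462, 1.744), "female": _s(1.583, 0.056, 1.443, 1.681)},
        "pmi_x": {"male": _s(0.461, 0.006, 0.447, 0.470), "female": _s(0.465, 0.003, 0.460, 0.471)},
        "pmi_y": {"male": _s(0.451, 0.005, 0.443, 0.463), "female": _s(0.456, 0.003, 0.450, 0.466)},
        "pmi_z": {"male": _s(0.088, 0.009, 0.067, 0.103), "female": _s(0.078, 0.005, 0.068, 0.089)},
    },
    ("left", 2): {
        "Ln": {"male": _s(0.659, 0.015, 0.629, 0.687), "female": _s(0.666, 0.010, 0.639, 0.686)},
        "Wn": {"male": _s(0.145, 0.008, 0.133, 0.164), "female": _s(0.143, 0.006, 0.132, 0.157)},
        "Hn": {"male": _s(0.196, 0.010, 0.178, 0.220), "female": _s(0.191, 0.008, 0.178, 0.218)},
        "sa_v": {"male": _s(0.362, 0.022, 0.328, 0.420), "female": _s(0.420, 0.026, 0.359, 0.470)},
        "density": {"male": _s(1.710, 0.078, 1.522, 1.907), "female": _s(1.748, 0.077, 1.592, 1.909)},
        "pmi_x": {"male": _s(0.478, 0.003, 0.472, 0.485), "female": _s(0.480, 0.002, 0.476, 0.483)},
        "pmi_y": {"male": _s(0.488, 0.002, 0.484, 0.491), "female": _s(0.489, 0.001, 0.486, 0.491)},
        "pmi_z": {"male": _s(0.034, 0.004, 0.024, 0.042), "female": _s(0.031, 0.003, 0.026, 0.038)},
    },
    ("right", 2): {
        "Ln": {"male": _s(0.658, 0.015, 0.624, 0.693), "female": _s(0.665, 0.011, 0.637, 0.681)},
        "Wn": {"male": _s(0.145, 0.008, 0.129, 0.162), "female": _s(0.142, 0.007, 0.122, 0.157)},
        "Hn": {"male": _s(0.197, 0.010, 0.173, 0.219), "female": _s(0.193, 0.008, 0.176, 0.207)},
        "sa_v": {"male": _s(0.359, 0.020, 0.332, 0.413), "female": _s(0.421, 0.027, 0.366, 0.487)},
        "density": {"male": _s(1.710, 0.085, 1.522, 1.913), "female": _s(1.730, 0.069, 1.586, 1.860)},
        "pmi_x": {"male": _s(0.478, 0.003, 0.472, 0.485), "female": _s(0.480, 0.002, 0.477, 0.482)},
        "pmi_y": {"male": _s(0.487, 0.003, 0.474, 0.490), "female": _s(0.489, 0.001, 0.486, 0.492)},
        "pmi_z": {"male": _s(0.035, 0.001, 0.026, 0.044), "female": _s(0.031, 0.002, 0.026, 0.037)},
    },
    ("left", 3): {
        "Ln": {"male": _s(0.663, 0.013, 0.636, 0.687), "female": _s(0.672, 0.010, 0.650, 0.690)},
        "Wn": {"male": _s(0.139, 0.008, 0.125, 0.156), "female": _s(0.136, 0.006, 0.123, 0.152)},
        "Hn": {"male": _s(0.198, 0.009, 0.178, 0.222), "female": _s(0.192, 0.008, 0.173, 0.206)},
        "sa_v": {"male": _s(0.386, 0.018, 0.348, 0.417), "female": _s(0.450, 0.021, 0.407, 0.502)},
        "density": {"male": _s(1.661, 0.077, 1.502, 1.844), "female": _s(1.666, 0.068, 1.514, 1.777)},
        "pmi_x": {"male": _s(0.477, 0.003, 0.470, 0.484), "female": _s(0.479, 0.002, 0.476, 0.483)},
        "pmi_y": {"male": _s(0.489, 0.002, 0.486, 0.492), "female": _s(0.490, 0.001, 0.488, 0.492)},
        "pmi_z": {"male": _s(0.034, 0.004, 0.024, 0.044), "female": _s(0.031, 0.003, 0.027, 0.035)},
    },
    ("right", 3): {
        "Ln": {"male": _s(0.663, 0.014, 0.634, 0.684), "female": _s(0.673, 0.012, 0.647, 0.692)},
        "Wn": {"male": _s(0.139, 0.008, 0.128, 0.156), "female": _s(0.136, 0.007, 0.121, 0.152)},
        "Hn": {"male": _s(0.198, 0.009, 0.180, 0.221), "female": _s(0.192, 0.009, 0.172, 0.213)},
        "sa_v": {"male": _s(0.383, 0.016, 0.346, 0.407), "female": _s(0.448, 0.022, 0.409, 0.504)},
        "density": {"male": _s(1.660, 0.075, 1.496, 1.803), "female": _s(1.652, 0.064, 1.516, 1.775)},
        "pmi_x": {"male": _s(0.477, 0.003, 0.469, 0.483), "female": _s(0.480, 0.002, 0.476, 0.483)},
        "pmi_y": {"male": _s(0.488, 0.002, 0.485, 0.492), "female": _s(0.490, 0.001, 0.487, 0.492)},
        "pmi_z": {"male": _s(0.035, 0.004, 0.025, 0.046), "female": _s(0.030, 0.003, 0.027, 0.036)},
    },
    ("left", 4): {
        "Ln": {"male": _s(0.670, 0.012, 0.645, 0.696), "female": _s(0.680, 0.010, 0.659, 0.699)},
        "Wn": {"male": _s(0.148, 0.007, 0.135, 0.166), "female": _s(0.146, 0.008, 0.135, 0.168)},
        "Hn": {"male": _s(0.182, 0.010, 0.160, 0.209), "female": _s(0.174, 0.008, 0.161, 0.189)},
        "sa_v": {"male": _s(0.377, 0.016, 0.341, 0.418), "female": _s(0.437, 0.023, 0.392, 0.487)},
        "density": {"male": _s(1.631, 0.077, 1.429, 1.760), "female": _s(1.624, 0.061, 1.458, 1.751)},
        "pmi_x": {"male": _s(0.479, 0.003, 0.473, 0.486), "female": _s(0.481, 0.002, 0.477, 0.484)},
        "pmi_y": {"male": _s(0.487, 0.002, 0.484, 0.492), "female": _s(0.488, 0.001, 0.485, 0.490)},
        "pmi_z": {"male": _s(0.034, 0.004, 0.023, 0.041), "female": _s(0.031, 0.003, 0.026, 0.037)},
    },
    ("right", 4): {
        "Ln": {"male": _s(0.668, 0.013, 0.638, 0.697), "female": _s(0.680, 0.011, 0.656, 0.697)},
        "Wn": {"male": _s(0.149, 0.006, 0.138, 0.159), "female": _s(0.145, 0.007, 0.127, 0.160)},
        "Hn": {"male": _s(0.183, 0.010, 0.163, 0.213), "female": _s(0.175, 0.007, 0.161, 0.192)},
        "sa_v": {"male": _s(0.375, 0.016, 0.335, 0.408), "female": _s(0.437, 0.023, 0.392, 0.484)},
        "density": {"male": _s(1.633, 0.071, 1.429, 1.731), "female": _s(1.620, 0.053, 1.482, 1.718)},
        "pmi_x": {"male": _s(0.478, 0.003, 0.472, 0.484), "female": _s(0.481, 0.002, 0.477, 0.486)},
        "pmi_y": {"male": _s(0.487, 0.002, 0.483, 0.491), "female": _s(0.488, 0.002, 0.482, 0.491)},
        "pmi_z": {"male": _s(0.034, 0.004, 0.026, 0.041), "female": _s(0.031, 0.003, 0.026, 0.036)},
    },
    ("left", 5): {
        "Ln": {"male": _s(0.658, 0.014, 0.630, 0.706), "female": _s(0.667, 0.012, 0.642, 0.692)},
        "Wn": {"male": _s(0.192, 0.010, 0.163, 0.207), "female": _s(0.190, 0.008, 0.173, 0.205)},
        "Hn": {"male": _s(0.150, 0.008, 0.131, 0.173), "female": _s(0.143, 0.007, 0.130, 0.158)},
        "sa_v": {"male": _s(0.346, 0.017, 0.313, 0.388), "female": _s(0.398, 0.023, 0.354, 0.444)},
        "density": {"male": _s(1.682, 0.077, 1.466, 1.798), "female": _s(1.666, 0.053, 1.569, 1.813)},
        "pmi_x": {"male": _s(0.484, 0.003, 0.479, 0.491), "female": _s(0.485, 0.002, 0.481, 0.487)},
        "pmi_y": {"male": _s(0.475, 0.004, 0.468, 0.487), "female": _s(0.477, 0.003, 0.470, 0.482)},
        "pmi_z": {"male": _s(0.041, 0.006, 0.022, 0.051), "female": _s(0.038, 0.004, 0.032, 0.049)},
    },
    ("right", 5): {
        "Ln": {"male": _s(0.661, 0.013, 0.637, 0.701), "female": _s(0.668, 0.010, 0.642, 0.693)},
        "Wn": {"male": _s(0.191, 0.011, 0.164, 0.206), "female": _s(0.189, 0.007, 0.175, 0.203)},
        "Hn": {"male": _s(0.148, 0.008, 0.134, 0.168), "female": _s(0.143, 0.007, 0.130, 0.155)},
        "sa_v": {"male": _s(0.345, 0.016, 0.307, 0.370), "female": _s(0.398, 0.023, 0.358, 0.450)},
        "density": {"male": _s(1.682, 0.070, 1.466, 1.788), "female": _s(1.653, 0.053, 1.549, 1.800)},
        "pmi_x": {"male": _s(0.484, 0.002, 0.480, 0.489), "female": _s(0.485, 0.002, 0.482, 0.488)},
        "pmi_y": {"male": _s(0.476, 0.004, 0.468, 0.484), "female": _s(0.477, 0.003, 0.472, 0.482)},
        "pmi_z": {"male": _s(0.040, 0.006, 0.027, 0.052), "female": _s(0.038, 0.004, 0.031, 0.046)},
    },
}


#: Published discriminant functions, transcribed verbatim.
#: Keyed (side, metatarsal); coefficient order matches ``variables``.
PUBLISHED_FUNCTIONS: dict[tuple[str, int], dict] = {
    ("left", 1): dict(
        variables=("sa_v", "density", "Hn"),
        coefficients=(-72.779, 13.129, 64.683),
        constant=-13.556,
        structure_matrix=(-0.686, 0.144, 0.278),
        std_coefficients=(-1.098, 0.745, 0.504),
        centroid_male=1.536,
        centroid_female=-1.589,
        sectioning_point=-0.027,
        wilks_lambda=0.283,
        chi_square=69.969,
    ),
    ("left", 2): dict(
        variables=("sa_v", "Hn"),
        coefficients=(39.926, -35.974),
        constant=-8.664,
        structure_matrix=(0.946, -0.242),
        std_coefficients=(0.974, -0.325),
        centroid_male=-1.257,
        centroid_female=1.257,
        sectioning_point=0.000,
        wilks_lambda=0.380,
        chi_square=55.225,
    ),
    ("left", 3): dict(
        variables=("sa_v", "Hn"),
        coefficients=(51.104, -38.990),
        constant=-13.755,
        structure_matrix=(0.947, -0.210),
        std_coefficients=(0.984, -0.324),
        centroid_male=-1.746,
        centroid_female=1.746,
        sectioning_point=0.000,
        wilks_lambda=0.241,
        chi_square=81.189,
    ),
    ("left", 4): dict(
        variables=("sa_v",),
        coefficients=(50.593,),
        constant=-20.593,
        structure_matrix=(1.000,),
        std_coefficients=(1.000,),
        centroid_male=-1.499,
        centroid_female=1.499,
        sectioning_point=0.000,
        wilks_lambda=0.301,
        chi_square=69.087,
    ),
    ("left", 5): dict(
        variables=("sa_v", "density"),
        coefficients=(51.174, -4.971),
        constant=-10.718,
        structure_matrix=(0.948, -0.090),
        std_coefficients=(1.024, -0.327),
        centroid_male=-1.355,
        centroid_female=1.355,
        sectioning_point=0.000,
        wilks_lambda=0.345,
        chi_square=60.676,
    ),
    ("right", 1): dict(
        variables=("sa_v", "pmi_z", "density"),
        coefficients=(-61.716, 77.849, 8.292),
        constant=-2.848,
        structure_matrix=(-0.728, 0.504, 0.127),
        std_coefficients=(-0.911, 0.535, 0.530),
        centroid_male=1.554,
        centroid_female=-1.503,
        sectioning_point=0.026,
        wilks_lambda=0.293,
        chi_square=68.207,
    ),
    ("right", 2): dict(
        variables=("sa_v", "pmi_z"),
        coefficients=(37.552, -124.899),
        constant=-10.559,
        structure_matrix=(0.912, -0.463),
        std_coefficients=(0.888, -0.410),
        centroid_male=-1.442,
        centroid_female=1.442,
        sectioning_point=0.000,
        wilks_lambda=0.317,
        chi_square=65.407,
    ),
    ("right", 3): dict(
        variables=("sa_v", "Hn"),
        coefficients=(52.538, -35.799),
        constant=-14.859,
        structure_matrix=(0.944, -0.180),
        std_coefficients=(0.995, -0.333),
        centroid_male=-1.828,
        centroid_female=1.828,
        sectioning_point=0.000,
        wilks_lambda=0.224,
        chi_square=85.167,
    ),
    ("right", 4): dict(
        variables=("sa_v", "density", "Hn"),
        coefficients=(54.196, -8.403, -37.812),
        constant=-1.557,
        structure_matrix=(0.822, -0.058, -0.227),
        std_coefficients=(1.087, -0.528, -0.333),
        centroid_male=-1.890,
        centroid_female=1.890,
        sectioning_point=0.000,
        wilks_lambda=0.213,
        chi_square=87.386,
    ),
    ("right", 5): dict(
        variables=("sa_v", "density"),
        coefficients=(55.060, -9.850),
        constant=-4.021,
        structure_matrix=(0.833, -0.147),
        std_coefficients=(1.092, -0.610),
        centroid_male=-1.590,
        centroid_female=1.590,
        sectioning_point=0.000,
        wilks_lambda=0.277,
        chi_square=73.259,
    ),
}


#: Pooled anthropometrics of the reference cohort (30 M + 30 F young adults).
SUBJECT_SUMMARY = {
    "age_years": (20.9, 3.0),
    "height_cm": (170.9, 9.9),
    "weight_kg": (62.5, 10.6),
}

# Per-sex height/weight are not published for the reference cohort; these
# defaults are chosen so the pooled 30+30 cohort matches SUBJECT_SUMMARY.
DEFAULT_COVARIATES = {
    "male": {"height_cm": (177.5, 6.0), "weight_kg": (68.5, 8.0)},
    "female": {"height_cm": (164.3, 6.0), "weight_kg": (56.5, 6.0)},
}


def cohort_means(side: str, metatarsal: int, sex: str) -> dict[str, float]:
    """Published per-variable means for one sex of one bone."""
    stats = COHORT_STATS[(side, metatarsal)]
    return {v: stats[v][sex].mean for v in VARIABLES}
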