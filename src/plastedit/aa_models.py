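"""Published amino-acid substitution model constants.

Exchangeabilities are the strict lower triangle in column-major order over
the PAML residue order ``ARNDCQEGHILKMFPSTWYV`` (190 values); frequencies
are the models' own equilibrium frequencies in the same order.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

LG_EXCHANGEABILITIES = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894,
    1.038545, 2.066040, 0.358858, 0.149830, 0.395337,
    0.536518, 1.124035, 0.253701, 1.177651, 4.727182,
    2.139501, 0.180717, 0.218959, 2.547870, 0.751878,
    0.123954, 0.534551, 2.807908, 0.363970, 0.390192,
    2.426601, 0.126991, 0.301848, 6.326067, 0.484133,
    0.052722, 0.332533, 0.858151, 0.578987, 0.593607,
    0.314440, 0.170887, 5.076149, 0.528768, 1.695752,
    0.541712, 1.437645, 4.509238, 0.191503, 0.068427,
    2.145078, 0.371004, 0.089525, 0.161787, 4.008358,
    2.000679, 0.045376, 0.612025, 0.083688, 0.062556,
    0.523386, 5.243870, 0.844926, 0.927114, 0.010690,
    0.015076, 0.282959, 0.025548, 0.017416, 0.394456,
    1.240275, 0.425860, 0.029890, 0.135107, 0.037967,
    0.084808, 0.003499, 0.569265, 0.640543, 0.320627,
    0.594007, 0.013266, 0.893680, 1.105251, 0.075382,
    2.784478, 1.143480, 0.670128, 1.165532, 1.959291,
    4.128591, 0.267959, 4.813505, 0.072854, 0.582457,
    3.234294, 1.672569, 0.035855, 0.624294, 1.223828,
    1.080136, 0.236199, 0.257336, 0.210332, 0.348847,
    0.423881, 0.044265, 0.069673, 1.807177, 0.173735,
    0.018811, 0.419409, 0.611973, 0.604545, 0.077852,
    0.120037, 0.245034, 0.311484, 0.008705, 0.044261,
    0.296636, 0.139538, 0.089586, 0.196961, 1.739990,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882,
    0.366317, 0.697264, 0.442472, 0.682139, 0.508851,
    0.990012, 0.584262, 0.597054, 5.306834, 0.119013,
    4.145067, 0.159069, 4.273607, 1.112727, 0.078281,
    0.064105, 1.033739, 0.111660, 0.232523, 10.649107,
    0.137500, 6.312358, 2.592692, 0.249060, 0.182287,
    0.302936, 0.619632, 0.299648, 1.702745, 0.656604,
    0.023918, 0.390322, 0.748683, 1.136863, 0.049906,
    0.131932, 0.185202, 1.798853, 0.099849, 0.346960,
    2.020366, 0.696175, 0.481306, 1.898718, 0.094464,
    0.361819, 0.165001, 2.457121, 7.803902, 0.654683,
    1.338132, 0.571468, 0.095131, 0.089613, 0.296501,
    6.472279, 0.248862, 0.400547, 0.098369, 0.140825,
    0.245841, 2.188158, 3.151815, 0.189510, 0.249313,
]

LG_FREQUENCIES = [
    0.079066, 0.055941, 0.041977, 0.053052, 0.012937,
    0.040767, 0.071586, 0.057337, 0.022355, 0.062157,
    0.099081, 0.064600, 0.022951, 0.042302, 0.044040,
    0.061197, 0.053287, 0.012066, 0.034155, 0.069147,
]

WAG_EXCHANGEABILITIES = [
    0.551571, 0.509848, 0.738998, 1.027040, 0.908598,
    1.582850, 1.416720, 0.316954, 0.193335, 0.397915,
    0.906265, 0.893496, 0.210494, 1.438550, 3.370790,
    2.121110, 0.113133, 0.240735, 2.006010, 0.635346,
    0.147304, 0.528191, 3.035500, 0.439157, 0.584665,
    2.137150, 0.186979, 0.497671, 5.351420, 0.683162,
    0.102711, 0.679489, 1.224190, 0.554413, 1.163920,
    0.381533, 0.251849, 5.429420, 0.265256, 1.543640,
    0.947198, 1.125560, 3.956290, 0.554236, 0.131528,
    3.012010, 0.198221, 0.096162, 0.195081, 3.974230,
    2.030060, 0.071917, 1.086000, 0.196246, 0.030295,
    0.616783, 6.174160, 0.865584, 0.930676, 0.039437,
    0.084805, 0.479855, 0.103754, 0.046730, 0.423984,
    1.071760, 0.374866, 0.129767, 0.325711, 0.152335,
    0.098818, 0.021352, 0.306674, 0.248972, 0.170135,
    0.384287, 0.074034, 0.390482, 0.398020, 0.109404,
    1.407660, 0.512984, 0.717070, 0.543833, 1.002140,
    5.469470, 0.330052, 4.294110, 0.113917, 0.869489,
    3.894900, 1.545260, 0.099921, 0.933372, 1.028870,
    0.857928, 0.215737, 0.227710, 0.301281, 0.567717,
    0.570025, 0.127395, 0.154263, 2.584430, 0.315124,
    0.081134, 0.682355, 0.704939, 0.822765, 0.156557,
    0.196303, 0.588731, 0.249410, 0.030450, 0.061304,
    0.373558, 0.174100, 0.049931, 0.243570, 1.341820,
    0.225833, 0.336983, 0.103604, 0.187247, 0.138190,
    0.499462, 0.890432, 0.404141, 0.679371, 0.696198,
    0.740169, 0.473307, 0.262569, 3.873440, 0.118358,
    3.170970, 0.323832, 4.257460, 1.059470, 0.099929,
    0.319440, 1.458160, 0.212483, 0.420170, 7.821300,
    0.257555, 4.854020, 2.115170, 0.415844, 0.344739,
    0.326622, 0.665309, 0.398618, 1.800340, 0.934276,
    0.088836, 0.556896, 0.967130, 1.386980, 0.137505,
    0.133264, 0.305434, 1.190630, 0.171329, 0.493905,
    1.516120, 0.515706, 0.428437, 2.058450, 0.161444,
    0.545931, 0.171903, 1.529640, 6.454280, 0.649892,
    1.613280, 0.795384, 0.139405, 0.216046, 0.314887,
    4.378020, 0.523742, 0.786993, 0.232739, 0.110864,
    0.291148, 1.388230, 2.485390, 0.365369, 0.314730,
]

WAG_FREQUENCIES = [
    0.086628, 0.043972, 0.039089, 0.057045, 0.019308,
    0.036728, 0.058059, 0.083252, 0.024431, 0.048466,
    0.086209, 0.062029, 0.019503, 0.038432, 0.045763,
    0.069518, 0.061013, 0.014386, 0.035274, 0.070896,
]
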