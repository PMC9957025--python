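# Empirical amino-acid exchangeability tables (PAML residue order:
# A R N D C Q E G H I L K M F P S T W Y V).
# Row-major lower-triangle exchangeabilities s[i][j] (i>j, PAML .dat
# layout) and model stationary frequencies, as published:
# WAG: Whelan & Goldman 2001; BLOSUM62: Henikoff & Henikoff 1992;
# VT: Mueller & Vingron 2000; HIVb: Nickle et al. 2007;
# LG: Le & Gascuel 2008; JTT: Jones et al. 1992; Dayhoff: Dayhoff et al. 1978.

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

EXCHANGEABILITIES = {
    "WAG": [
        [0.551571],
        [0.509848, 0.635346],
        [0.738998, 0.147304, 5.42942],
        [1.02704, 0.528191, 0.265256, 0.0302949],
        [0.908598, 3.0355, 1.54364, 0.616783, 0.0988179],
        [1.58285, 0.439157, 0.947198, 6.17416, 0.021352, 5.46947],
        [1.41672, 0.584665, 1.12556, 0.865584, 0.306674, 0.330052, 0.567717],
        [0.316954, 2.13715, 3.95629, 0.930676, 0.248972, 4.29411, 0.570025, 0.24941],
        [0.193335, 0.186979, 0.554236, 0.039437, 0.170135, 0.113917, 0.127395, 0.0304501, 0.13819],
        [0.397915, 0.497671, 0.131528, 0.0848047, 0.384287, 0.869489, 0.154263, 0.0613037, 0.499462, 3.17097],
        [0.906265, 5.35142, 3.01201, 0.479855, 0.0740339, 3.8949, 2.58443, 0.373558, 0.890432, 0.323832, 0.257555],
        [0.893496, 0.683162, 0.198221, 0.103754, 0.390482, 1.54526, 0.315124, 0.1741, 0.404141, 4.25746, 4.85402, 0.934276],
        [0.210494, 0.102711, 0.0961621, 0.0467304, 0.39802, 0.0999208, 0.0811339, 0.049931, 0.679371, 1.05947, 2.11517, 0.088836, 1.19063],
        [1.43855, 0.679489, 0.195081, 0.423984, 0.109404, 0.933372, 0.682355, 0.24357, 0.696198, 0.0999288, 0.415844, 0.556896, 0.171329, 0.161444],
        [3.37079, 1.22419, 3.97423, 1.07176, 1.40766, 1.02887, 0.704939, 1.34182, 0.740169, 0.31944, 0.344739, 0.96713, 0.493905, 0.545931, 1.61328],
        [2.12111, 0.554413, 2.03006, 0.374866, 0.512984, 0.857928, 0.822765, 0.225833, 0.473307, 1.45816, 0.326622, 1.38698, 1.51612, 0.171903, 0.795384, 4.37802],
        [0.113133, 1.16392, 0.0719167, 0.129767, 0.71707, 0.215737, 0.156557, 0.336983, 0.262569, 0.212483, 0.665309, 0.137505, 0.515706, 1.52964, 0.139405, 0.523742, 0.110864],
        [0.240735, 0.381533, 1.086, 0.325711, 0.543833, 0.22771, 0.196303, 0.103604, 3.87344, 0.42017, 0.398618, 0.133264, 0.428437, 6.45428, 0.216046, 0.786993, 0.291148, 2.48539],
        [2.00601, 0.251849, 0.196246, 0.152335, 1.00214, 0.301281, 0.588731, 0.187247, 0.118358, 7.8213, 1.80034, 0.305434, 2.05845, 0.649892, 0.314887, 0.232739, 1.38823, 0.365369, 0.31473],
    ],
    "BLOSUM62": [
        [0.7357903897],
        [0.4853910555, 1.297446705],
        [0.5431618209, 0.5009644086, 3.180100048],
        [1.45999531, 0.2278265742, 0.3973589499, 0.2408366148],
        [1.199705705, 3.02083361, 1.839216147, 1.190945703, 0.3298015046],
        [1.170949043, 1.36057419, 1.240488509, 3.761625208, 0.1407488918, 5.528919178],
        [1.955883575, 0.4187633085, 1.355872344, 0.798473249, 0.4182031923, 0.6098463054, 0.4235799922],
        [0.716241445, 1.456141166, 2.414501434, 0.778142664, 0.3540581098, 2.435341131, 1.626891057, 0.539859125],
        [0.6058990037, 0.2320364451, 0.2830173263, 0.4185557325, 0.7748940228, 0.2362024512, 0.1868480469, 0.1892962924, 0.2527184479],
        [0.8000165305, 0.6227116697, 0.2118881596, 0.2181315776, 0.8318426401, 0.5807370932, 0.3726251751, 0.2177211592, 0.3480722098, 3.890963773],
        [1.295201267, 5.411115141, 1.593137043, 1.032447925, 0.2850788009, 3.945277675, 2.802427152, 0.7520424403, 1.022507036, 0.4061935866, 0.4455702743],
        [1.253758267, 0.9836929875, 0.6484412788, 0.222621898, 0.7676888235, 2.494896077, 0.5554153975, 0.4594361736, 0.9843115254, 3.364797763, 6.03055938, 1.073061184],
        [0.4929646797, 0.3716446932, 0.3548612492, 0.2817306942, 0.4413374712, 0.1443569598, 0.2914090842, 0.3681664645, 0.7145337039, 1.517359326, 2.064839703, 0.2669247505, 1.773855169],
        [1.173275901, 0.4481336617, 0.4948870437, 0.730628273, 0.3560084988, 0.8585705757, 0.9265639348, 0.5040865995, 0.5270073392, 0.3883554092, 0.3745556875, 1.047383451, 0.4541236251, 0.2335979096],
        [4.325092687, 1.122783104, 2.904101656, 1.582754142, 1.197188415, 1.934870925, 1.769893239, 1.509326253, 1.117029763, 0.3575444125, 0.3529691845, 1.752165918, 0.9187234157, 0.5400276448, 1.169129578],
        [1.729178019, 0.9146659546, 1.898173635, 0.9341875094, 1.119831359, 1.277480295, 1.071097236, 0.6414360114, 0.5854070902, 1.179091197, 0.9152598577, 1.303875201, 1.488548054, 0.4882061188, 1.005451683, 5.151556292],
        [0.4658393677, 0.4263823101, 0.1914820462, 0.1453450463, 0.5276644189, 0.7586538086, 0.4076356489, 0.5083589246, 0.3012486008, 0.3419857875, 0.6914746346, 0.3322430406, 0.8881010982, 2.074324893, 0.25221483, 0.3879256221, 0.5131281269],
        [0.7182066976, 0.7205174412, 0.538222519, 0.261422209, 0.4702377337, 0.9589897429, 0.5967193003, 0.308055737, 4.218953969, 0.6746170932, 0.8112458563, 0.7179934869, 0.9516821622, 6.747260431, 0.3694053194, 0.7967515208, 0.8010102432, 4.054419007],
        [2.187774522, 0.4383883438, 0.312858798, 0.2581292894, 1.116352479, 0.5307857901, 0.5242538463, 0.2533407902, 0.2015559718, 8.311839405, 2.231405689, 0.4981384753, 2.575850755, 0.8381196102, 0.4969084107, 0.5619254574, 2.253074051, 0.2665087314, 1],
    ],
    "VT": [
        [0.233108],
        [0.199097, 0.210797],
        [0.265145, 0.105191, 0.883422],
        [0.227333, 0.031726, 0.027495, 0.010313],
        [0.310084, 0.493763, 0.2757, 0.205842, 0.004315],
        [0.567957, 0.25524, 0.270417, 1.599461, 0.005321, 0.960976],
        [0.876213, 0.156945, 0.362028, 0.311718, 0.050876, 0.12866, 0.250447],
        [0.078692, 0.213164, 0.290006, 0.134252, 0.016695, 0.315521, 0.104458, 0.058131],
        [0.222972, 0.08151, 0.087225, 0.01172, 0.046398, 0.054602, 0.046589, 0.051089, 0.020039],
        [0.42463, 0.192364, 0.069245, 0.060863, 0.091709, 0.24353, 0.151924, 0.087056, 0.103552, 2.08989],
        [0.393245, 1.755838, 0.50306, 0.261101, 0.004067, 0.738208, 0.88863, 0.193243, 0.153323, 0.093181, 0.201204],
        [0.21155, 0.08793, 0.05742, 0.012182, 0.02369, 0.120801, 0.058643, 0.04656, 0.021157, 0.493845, 1.105667, 0.096474],
        [0.116646, 0.042569, 0.039769, 0.016577, 0.051127, 0.026235, 0.028168, 0.050143, 0.079807, 0.32102, 0.946499, 0.038261, 0.173052],
        [0.399143, 0.12848, 0.083956, 0.160063, 0.011137, 0.15657, 0.205134, 0.124492, 0.078892, 0.054797, 0.169784, 0.212302, 0.010363, 0.042564],
        [1.817198, 0.292327, 0.847049, 0.461519, 0.17527, 0.358017, 0.406035, 0.612843, 0.167406, 0.081567, 0.214977, 0.400072, 0.090515, 0.138119, 0.430431],
        [0.877877, 0.204109, 0.471268, 0.178197, 0.079511, 0.248992, 0.321028, 0.136266, 0.101117, 0.376588, 0.243227, 0.446646, 0.184609, 0.08587, 0.207143, 1.767766],
        [0.030309, 0.046417, 0.010459, 0.011393, 0.007732, 0.021248, 0.018844, 0.02399, 0.020009, 0.034954, 0.083439, 0.023321, 0.022019, 0.12805, 0.014584, 0.035933, 0.020437],
        [0.087061, 0.09701, 0.093268, 0.051664, 0.042823, 0.062544, 0.0552, 0.037568, 0.286027, 0.086237, 0.189842, 0.068689, 0.073223, 0.898663, 0.032043, 0.121979, 0.094617, 0.124746],
        [1.230985, 0.113146, 0.049824, 0.048769, 0.163831, 0.112027, 0.205868, 0.082579, 0.068575, 3.65443, 1.337571, 0.144587, 0.307309, 0.247329, 0.129315, 0.1277, 0.740372, 0.022134, 0.125733],
    ],
    "HIVB": [
        [0.307507],
        [0.005, 0.295543],
        [1.45504, 0.005, 17.6612],
        [0.123758, 0.351721, 0.0860642, 0.005],
        [0.0551128, 3.4215, 0.672052, 0.005, 0.005],
        [1.48135, 0.0749218, 0.0792633, 10.5872, 0.005, 2.5602],
        [2.13536, 3.65345, 0.323401, 2.83806, 0.897871, 0.0619137, 3.92775],
        [0.0847613, 9.04044, 7.64585, 1.9169, 0.240073, 7.05545, 0.11974, 0.005],
        [0.005, 0.677289, 0.680565, 0.0176792, 0.005, 0.005, 0.00609079, 0.005, 0.103111],
        [0.215256, 0.701427, 0.005, 0.00876048, 0.129777, 1.49456, 0.005, 0.005, 1.74171, 5.95879],
        [0.005, 20.45, 7.90443, 0.005, 0.005, 6.54737, 4.61482, 0.521705, 0.005, 0.322319, 0.0814995],
        [0.0186643, 2.51394, 0.005, 0.005, 0.005, 0.303676, 0.175789, 0.005, 0.005, 11.2065, 5.31961, 1.28246],
        [0.0141269, 0.005, 0.005, 0.005, 9.29815, 0.005, 0.005, 0.291561, 0.145558, 3.39836, 8.52484, 0.0342658, 0.188025],
        [2.12217, 1.28355, 0.00739578, 0.0342658, 0.005, 4.47211, 0.0120226, 0.005, 2.45318, 0.0410593, 2.07757, 0.0313862, 0.005, 0.005],
        [2.46633, 3.4791, 13.1447, 0.52823, 4.69314, 0.116311, 0.005, 4.38041, 0.382747, 1.21803, 0.927656, 0.504111, 0.005, 0.956472, 5.37762],
        [15.9183, 2.86868, 6.88667, 0.274724, 0.739969, 0.243589, 0.289774, 0.369615, 0.711594, 8.61217, 0.0437673, 4.67142, 4.94026, 0.0141269, 2.01417, 8.93107],
        [0.005, 0.991338, 0.005, 0.005, 2.63277, 0.026656, 0.005, 1.21674, 0.0695179, 0.005, 0.748843, 0.005, 0.089078, 0.829343, 0.0444506, 0.0248728, 0.005],
        [0.005, 0.00991826, 1.76417, 0.674653, 7.57932, 0.113033, 0.0792633, 0.005, 18.6943, 0.148168, 0.111986, 0.005, 0.005, 15.34, 0.0304381, 0.648024, 0.105652, 1.28022],
        [7.61428, 0.0812454, 0.026656, 1.04793, 0.420027, 0.0209153, 1.02847, 0.953155, 0.005, 17.7389, 1.41036, 0.265829, 6.8532, 0.723274, 0.005, 0.0749218, 0.709226, 0.005, 0.0410593],
    ],
    "LG": [
        [0.425093],
        [0.276818, 0.751878],
        [0.395144, 0.123954, 5.076149],
        [2.489084, 0.534551, 0.528768, 0.062556],
        [0.969894, 2.807908, 1.695752, 0.523386, 0.084808],
        [1.038545, 0.36397, 0.541712, 5.24387, 0.003499, 4.128591],
        [2.06604, 0.390192, 1.437645, 0.844926, 0.569265, 0.267959, 0.348847],
        [0.358858, 2.426601, 4.509238, 0.927114, 0.640543, 4.813505, 0.423881, 0.311484],
        [0.14983, 0.126991, 0.191503, 0.01069, 0.320627, 0.072854, 0.044265, 0.008705, 0.108882],
        [0.395337, 0.301848, 0.068427, 0.015076, 0.594007, 0.582457, 0.069673, 0.044261, 0.366317, 4.145067],
        [0.536518, 6.326067, 2.145078, 0.282959, 0.013266, 3.234294, 1.807177, 0.296636, 0.697264, 0.159069, 0.1375],
        [1.124035, 0.484133, 0.371004, 0.025548, 0.89368, 1.672569, 0.173735, 0.139538, 0.442472, 4.273607, 6.312358, 0.656604],
        [0.253701, 0.052722, 0.089525, 0.017416, 1.105251, 0.035855, 0.018811, 0.089586, 0.682139, 1.112727, 2.592692, 0.023918, 1.798853],
        [1.177651, 0.332533, 0.161787, 0.394456, 0.075382, 0.624294, 0.419409, 0.196961, 0.508851, 0.078281, 0.24906, 0.390322, 0.099849, 0.094464],
        [4.727182, 0.858151, 4.008358, 1.240275, 2.784478, 1.223828, 0.611973, 1.73999, 0.990012, 0.064105, 0.182287, 0.748683, 0.34696, 0.361819, 1.338132],
        [2.139501, 0.578987, 2.000679, 0.42586, 1.14348, 1.080136, 0.604545, 0.129836, 0.584262, 1.033739, 0.302936, 1.136863, 2.020366, 0.165001, 0.571468, 6.472279],
        [0.180717, 0.593607, 0.045376, 0.02989, 0.670128, 0.236199, 0.077852, 0.268491, 0.597054, 0.11166, 0.619632, 0.049906, 0.696175, 2.457121, 0.095131, 0.248862, 0.140825],
        [0.218959, 0.31444, 0.612025, 0.135107, 1.165532, 0.257336, 0.120037, 0.054679, 5.306834, 0.232523, 0.299648, 0.131932, 0.481306, 7.803902, 0.089613, 0.400547, 0.245841, 3.151815],
        [2.54787, 0.170887, 0.083688, 0.037967, 1.959291, 0.210332, 0.245034, 0.076701, 0.119013, 10.649107, 1.702745, 0.185202, 1.898718, 0.654683, 0.296501, 0.098369, 2.188158, 0.18951, 0.249313],
    ],
    "JTT": [
        [58],
        [54, 45],
        [81, 16, 528],
        [56, 113, 34, 10],
        [57, 310, 86, 49, 9],
        [105, 29, 58, 767, 5, 323],
        [179, 137, 81, 130, 59, 26, 119],
        [27, 328, 391, 112, 69, 597, 26, 23],
        [36, 22, 47, 11, 17, 9, 12, 6, 16],
        [30, 38, 12, 7, 23, 72, 9, 6, 56, 229],
        [35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14],
        [54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65],
        [15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43],
        [194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17],
        [378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285],
        [475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477],
        [9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12],
        [11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71],
        [298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16],
    ],
    "DAYHOFF": [
        [27],
        [98, 32],
        [120, 0, 905],
        [36, 23, 0, 0],
        [89, 246, 103, 134, 0],
        [198, 1, 148, 1153, 0, 716],
        [240, 9, 139, 125, 11, 28, 81],
        [23, 240, 535, 86, 28, 606, 43, 10],
        [65, 64, 77, 24, 44, 18, 61, 0, 7],
        [41, 15, 34, 0, 0, 73, 11, 7, 44, 257],
        [26, 464, 318, 71, 0, 153, 83, 27, 26, 46, 18],
        [72, 90, 1, 0, 0, 114, 30, 17, 0, 336, 527, 243],
        [18, 14, 14, 0, 0, 0, 0, 15, 48, 196, 157, 0, 92],
        [250, 103, 42, 13, 19, 153, 51, 34, 94, 12, 32, 33, 17, 11],
        [409, 154, 495, 95, 161, 56, 79, 234, 35, 24, 17, 96, 62, 46, 245],
        [371, 26, 229, 66, 16, 53, 34, 30, 22, 192, 33, 136, 104, 13, 78, 550],
        [0, 201, 23, 0, 0, 0, 0, 0, 27, 0, 46, 0, 0, 76, 0, 75, 0],
        [24, 8, 95, 0, 96, 0, 22, 0, 127, 37, 28, 13, 0, 698, 0, 34, 42, 61],
        [208, 24, 15, 18, 49, 35, 37, 54, 44, 889, 175, 10, 258, 12, 48, 30, 157, 0, 28],
    ],
}

FREQUENCIES = {
    "WAG": [0.08662790866, 0.0439720044, 0.03908940391, 0.0570451057, 0.01930780193, 0.03672810367, 0.05805890581, 0.08325180833, 0.02443130244, 0.04846600485, 0.08620900862, 0.0620286062, 0.01950270195, 0.03843190384, 0.04576310458, 0.06951790695, 0.0610127061, 0.01438590144, 0.03527420353, 0.07089560709],
    "BLOSUM62": [0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068, 0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073],
    "VT": [0.07883692116, 0.05123794876, 0.04231295769, 0.05306594693, 0.01517498483, 0.03671296329, 0.06192393808, 0.07085192915, 0.02308197692, 0.06205593794, 0.09637090363, 0.05732394268, 0.02377097623, 0.0432959567, 0.04391095609, 0.0634029366, 0.0558969441, 0.01327198673, 0.0343989656, 0.0731009269],
    "HIVB": [0.06049022206, 0.06603966507, 0.04412781504, 0.04210904804, 0.02007589902, 0.05360648805, 0.07156744707, 0.07230823907, 0.02229394302, 0.06973062907, 0.0988511221, 0.05696821106, 0.01976831802, 0.02880944703, 0.04602528205, 0.05060433005, 0.05363681305, 0.03301160103, 0.02835024303, 0.06162523706],
    "LG": [0.07906592093, 0.05594094406, 0.04197695802, 0.05305194695, 0.01293698706, 0.04076695923, 0.07158592841, 0.05733694266, 0.02235497765, 0.06215693784, 0.09908090092, 0.0645999354, 0.02295097705, 0.0423019577, 0.04403995596, 0.0611969388, 0.05328694671, 0.01206598793, 0.03415496585, 0.06914693085],
    "JTT": [0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.0198029802, 0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624, 0.0919039081, 0.05867594132, 0.02382597617, 0.04012595987, 0.0509009491, 0.06876493124, 0.05856494144, 0.01426098574, 0.0321019679, 0.066004934],
    "DAYHOFF": [0.08712691287, 0.0409039591, 0.04043195957, 0.04687195313, 0.03347396653, 0.03825496175, 0.04952995047, 0.08861191139, 0.03361796638, 0.03688596311, 0.08535691464, 0.08048191952, 0.01475298525, 0.03977196023, 0.05067994932, 0.06957693042, 0.05854194146, 0.01049398951, 0.02991597008, 0.06471793528],
}
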