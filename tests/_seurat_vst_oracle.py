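"""Frozen oracle: per-gene vst standardized variances from R Seurat 5.3.0

Produced by FindVariableFeatures(selection.method="vst") on the synthetic
60-gene x 40-cell negative-binomial fixture generated by
SimulationConfig(n_genes=60, n_network_genes=20, n_cells=40, nb_mean=2.0,
nb_dispersion=2.0, potency_effect=2.0, seed=42). The counts checksum
(sum = 6444.0) guards against generator drift.
"""

SEURAT_VST_STANDARDIZED_VARIANCE = {
    'G0001': 0.615448620485249,
    'G0002': 1.15343253405652,
    'G0003': 1.19896619384714,
    'G0004': 0.584925512263086,
    'G0005': 1.04720559818697,
    'G0006': 0.801697075260982,
    'G0007': 1.66712908580453,
    'G0008': 1.15386092457662,
    'G0009': 0.897393918398497,
    'G0010': 1.11286547846981,
    'G0011': 1.08764687148421,
    'G0012': 1.09550432490403,
    'G0013': 1.18065206221103,
    'G0014': 0.815410805587202,
    'G0015': 1.08546690899149,
    'G0016': 0.75796142846089,
    'G0017': 0.950748852602112,
    'G0018': 1.33521329835681,
    'G0019': 0.730466796036869,
    'G0020': 0.785057971933016,
    'G0021': 1.32615247543041,
    'G0022': 0.997296759389477,
    'G0023': 1.1974679996863,
    'G0024': 1.1725476857394,
    'G0025': 0.86652266330376,
    'G0026': 0.830249412151497,
    'G0027': 1.15489865926236,
    'G0028': 1.08068258113815,
    'G0029': 1.01942397175858,
    'G0030': 1.29248046819468,
    'G0031': 0.718044704552599,
    'G0032': 0.862810406247131,
    'G0033': 1.22853540801501,
    'G0034': 0.842742522964761,
    'G0035': 0.976736571172694,
    'G0036': 1.62259662890093,
    'G0037': 1.17700009182842,
    'G0038': 0.771092024104339,
    'G0039': 0.90916949485554,
    'G0040': 1.19211765403353,
    'G0041': 0.846690219195619,
    'G0042': 1.04450311075742,
    'G0043': 0.960980522705476,
    'G0044': 0.983990598490351,
    'G0045': 0.686955934682261,
    'G0046': 0.904534586996802,
    'G0047': 0.839354649184025,
    'G0048': 2.02187114862216,
    'G0049': 0.829135389748875,
    'G0050': 0.660697868266334,
    'G0051': 0.943016852446447,
    'G0052': 1.4839251173569,
    'G0053': 0.951498738325004,
    'G0054': 0.904153633095597,
    'G0055': 1.17431868357121,
    'G0056': 0.925939871232807,
    'G0057': 0.790690612502336,
    'G0058': 0.876971562040039,
    'G0059': 1.0106029202886,
    'G0060': 1.13761306062151,
}
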