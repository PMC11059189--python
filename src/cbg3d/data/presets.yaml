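# Stage presets for the synthetic single-cell contact generator.
#
# Keys per preset:
#   genome       packaged genome fixture the preset is meant for (human|mouse)
#   f_ultra      target fraction of intra-chromosomal contacts >= 10 Mb
#   alpha        power-law slope of the short-range distance component
#   f_inter      fraction of contacts that are inter-chromosomal
#   rho          same-compartment partner preference in [0, 1]
#   drift_level  progression along the compartment-drift trajectory in [0, 1]
#                (0 = baseline track, 1 = drifted bins fully at their targets)
#   hub          optional inter-chromosomal hub: a chromosome set and/or
#                explicit chromosome pairs whose raw pair weight is `weight`
#                (matrix is renormalized to mean 1 before use)
#
# f_ultra values for the granule stages and reference cell types follow the
# published per-cell-type ultra-long-range contact fractions; intermediate
# granule stages interpolate linearly between the S1 and S5 endpoints.
human_S1: {genome: human, f_ultra: 0.19, alpha: 1.0, f_inter: 0.02, rho: 0.7, drift_level: 0.0}
human_S2: {genome: human, f_ultra: 0.225, alpha: 1.0, f_inter: 0.03, rho: 0.7, drift_level: 0.25,
           hub: {chroms: [chr1, chr9, chr11, chr14, chr15, chr16, chr17, chr21, chr22], weight: 1.25}}
human_S3: {genome: human, f_ultra: 0.26, alpha: 1.0, f_inter: 0.04, rho: 0.7, drift_level: 0.5,
           hub: {chroms: [chr1, chr9, chr11, chr14, chr15, chr16, chr17, chr21, chr22], weight: 1.5}}
human_S4: {genome: human, f_ultra: 0.295, alpha: 1.0, f_inter: 0.05, rho: 0.7, drift_level: 0.75,
           hub: {chroms: [chr1, chr9, chr11, chr14, chr15, chr16, chr17, chr21, chr22], weight: 1.75}}
human_S5: {genome: human, f_ultra: 0.33, alpha: 1.0, f_inter: 0.06, rho: 0.7, drift_level: 1.0,
           hub: {chroms: [chr1, chr9, chr11, chr14, chr15, chr16, chr17, chr21, chr22], weight: 2.0}}
mouse_S1: {genome: mouse, f_ultra: 0.19, alpha: 1.0, f_inter: 0.02, rho: 0.7, drift_level: 0.0}
mouse_S2: {genome: mouse, f_ultra: 0.2275, alpha: 1.0, f_inter: 0.03, rho: 0.7, drift_level: 0.25,
           hub: {pairs: [[chr7, chr4], [chr7, chr5], [chr7, chr11], [chr7, chr17], [chr7, chr19]], weight: 1.25}}
mouse_S3: {genome: mouse, f_ultra: 0.265, alpha: 1.0, f_inter: 0.04, rho: 0.7, drift_level: 0.5,
           hub: {pairs: [[chr7, chr4], [chr7, chr5], [chr7, chr11], [chr7, chr17], [chr7, chr19]], weight: 1.5}}
mouse_S4: {genome: mouse, f_ultra: 0.3025, alpha: 1.0, f_inter: 0.05, rho: 0.7, drift_level: 0.75,
           hub: {pairs: [[chr7, chr4], [chr7, chr5], [chr7, chr11], [chr7, chr17], [chr7, chr19]], weight: 1.75}}
mouse_S5: {genome: mouse, f_ultra: 0.34, alpha: 1.0, f_inter: 0.06, rho: 0.7, drift_level: 1.0,
           hub: {pairs: [[chr7, chr4], [chr7, chr5], [chr7, chr11], [chr7, chr17], [chr7, chr19]], weight: 2.0}}
forebrain_mature: {genome: human, f_ultra: 0.16, alpha: 1.0, f_inter: 0.03, rho: 0.7, drift_level: 0.0}
purkinje_adult: {genome: mouse, f_ultra: 0.10, alpha: 1.0, f_inter: 0.03, rho: 0.7, drift_level: 0.0}
microglia: {genome: human, f_ultra: 0.34, alpha: 1.0, f_inter: 0.05, rho: 0.7, drift_level: 0.0}
oligodendrocyte_human: {genome: human, f_ultra: 0.29, alpha: 1.0, f_inter: 0.04, rho: 0.7, drift_level: 0.0}
oligodendrocyte_mouse: {genome: mouse, f_ultra: 0.27, alpha: 1.0, f_inter: 0.04, rho: 0.7, drift_level: 0.0}
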