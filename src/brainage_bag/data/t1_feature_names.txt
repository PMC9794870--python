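Left-Lateral-Ventricle
Right-Lateral-Ventricle
Left-Inf-Lat-Vent
Right-Inf-Lat-Vent
Left-Cerebellum-White-Matter
Right-Cerebellum-White-Matter
Left-Cerebellum-Cortex
Right-Cerebellum-Cortex
Left-Thalamus
Right-Thalamus
Left-Caudate
Right-Caudate
Left-Putamen
Right-Putamen
Left-Pallidum
Right-Pallidum
Left-Hippocampus
Right-Hippocampus
Left-Amygdala
Right-Amygdala
Left-Accumbens-area
Right-Accumbens-area
Left-VentralDC
Right-VentralDC
3rd-Ventricle
4th-Ventricle
Brain-Stem
CSF
WM-hypointensities
CC-Central
TotalBrainVolume
lh_caudalanteriorcingulate_surfacearea
lh_caudalanteriorcingulate_grayvol
lh_caudalanteriorcingulate_thicknessavg
rh_caudalanteriorcingulate_surfacearea
rh_caudalanteriorcingulate_grayvol
rh_caudalanteriorcingulate_thicknessavg
lh_caudalmiddlefrontal_surfacearea
lh_caudalmiddlefrontal_grayvol
lh_caudalmiddlefrontal_thicknessavg
rh_caudalmiddlefrontal_surfacearea
rh_caudalmiddlefrontal_grayvol
rh_caudalmiddlefrontal_thicknessavg
lh_cuneus_surfacearea
lh_cuneus_grayvol
lh_cuneus_thicknessavg
rh_cuneus_surfacearea
rh_cuneus_grayvol
rh_cuneus_thicknessavg
lh_entorhinal_surfacearea
lh_entorhinal_grayvol
lh_entorhinal_thicknessavg
rh_entorhinal_surfacearea
rh_entorhinal_grayvol
rh_entorhinal_thicknessavg
lh_fusiform_surfacearea
lh_fusiform_grayvol
lh_fusiform_thicknessavg
rh_fusiform_surfacearea
rh_fusiform_grayvol
rh_fusiform_thicknessavg
lh_inferiorparietal_surfacearea
lh_inferiorparietal_grayvol
lh_inferiorparietal_thicknessavg
rh_inferiorparietal_surfacearea
rh_inferiorparietal_grayvol
rh_inferiorparietal_thicknessavg
lh_inferiortemporal_surfacearea
lh_inferiortemporal_grayvol
lh_inferiortemporal_thicknessavg
rh_inferiortemporal_surfacearea
rh_inferiortemporal_grayvol
rh_inferiortemporal_thicknessavg
lh_isthmuscingulate_surfacearea
lh_isthmuscingulate_grayvol
lh_isthmuscingulate_thicknessavg
rh_isthmuscingulate_surfacearea
rh_isthmuscingulate_grayvol
rh_isthmuscingulate_thicknessavg
lh_lateraloccipital_surfacearea
lh_lateraloccipital_grayvol
lh_lateraloccipital_thicknessavg
rh_lateraloccipital_surfacearea
rh_lateraloccipital_grayvol
rh_lateraloccipital_thicknessavg
lh_lateralorbitofrontal_surfacearea
lh_lateralorbitofrontal_grayvol
lh_lateralorbitofrontal_thicknessavg
rh_lateralorbitofrontal_surfacearea
rh_lateralorbitofrontal_grayvol
rh_lateralorbitofrontal_thicknessavg
lh_lingual_surfacearea
lh_lingual_grayvol
lh_lingual_thicknessavg
rh_lingual_surfacearea
rh_lingual_grayvol
rh_lingual_thicknessavg
lh_medialorbitofrontal_surfacearea
lh_medialorbitofrontal_grayvol
lh_medialorbitofrontal_thicknessavg
rh_medialorbitofrontal_surfacearea
rh_medialorbitofrontal_grayvol
rh_medialorbitofrontal_thicknessavg
lh_middletemporal_surfacearea
lh_middletemporal_grayvol
lh_middletemporal_thicknessavg
rh_middletemporal_surfacearea
rh_middletemporal_grayvol
rh_middletemporal_thicknessavg
lh_parahippocampal_surfacearea
lh_parahippocampal_grayvol
lh_parahippocampal_thicknessavg
rh_parahippocampal_surfacearea
rh_parahippocampal_grayvol
rh_parahippocampal_thicknessavg
lh_paracentral_surfacearea
lh_paracentral_grayvol
lh_paracentral_thicknessavg
rh_paracentral_surfacearea
rh_paracentral_grayvol
rh_paracentral_thicknessavg
lh_parsopercularis_surfacearea
lh_parsopercularis_grayvol
lh_parsopercularis_thicknessavg
rh_parsopercularis_surfacearea
rh_parsopercularis_grayvol
rh_parsopercularis_thicknessavg
lh_parsorbitalis_surfacearea
lh_parsorbitalis_grayvol
lh_parsorbitalis_thicknessavg
rh_parsorbitalis_surfacearea
rh_parsorbitalis_grayvol
rh_parsorbitalis_thicknessavg
lh_parstriangularis_surfacearea
lh_parstriangularis_grayvol
lh_parstriangularis_thicknessavg
rh_parstriangularis_surfacearea
rh_parstriangularis_grayvol
rh_parstriangularis_thicknessavg
lh_pericalcarine_surfacearea
lh_pericalcarine_grayvol
lh_pericalcarine_thicknessavg
rh_pericalcarine_surfacearea
rh_pericalcarine_grayvol
rh_pericalcarine_thicknessavg
lh_postcentral_surfacearea
lh_postcentral_grayvol
lh_postcentral_thicknessavg
rh_postcentral_surfacearea
rh_postcentral_grayvol
rh_postcentral_thicknessavg
lh_posteriorcingulate_surfacearea
lh_posteriorcingulate_grayvol
lh_posteriorcingulate_thicknessavg
rh_posteriorcingulate_surfacearea
rh_posteriorcingulate_grayvol
rh_posteriorcingulate_thicknessavg
lh_precentral_surfacearea
lh_precentral_grayvol
lh_precentral_thicknessavg
rh_precentral_surfacearea
rh_precentral_grayvol
rh_precentral_thicknessavg
lh_precuneus_surfacearea
lh_precuneus_grayvol
lh_precuneus_thicknessavg
rh_precuneus_surfacearea
rh_precuneus_grayvol
rh_precuneus_thicknessavg
lh_rostralanteriorcingulate_surfacearea
lh_rostralanteriorcingulate_grayvol
lh_rostralanteriorcingulate_thicknessavg
rh_rostralanteriorcingulate_surfacearea
rh_rostralanteriorcingulate_grayvol
rh_rostralanteriorcingulate_thicknessavg
lh_rostralmiddlefrontal_surfacearea
lh_rostralmiddlefrontal_grayvol
lh_rostralmiddlefrontal_thicknessavg
rh_rostralmiddlefrontal_surfacearea
rh_rostralmiddlefrontal_grayvol
rh_rostralmiddlefrontal_thicknessavg
lh_superiorfrontal_surfacearea
lh_superiorfrontal_grayvol
lh_superiorfrontal_thicknessavg
rh_superiorfrontal_surfacearea
rh_superiorfrontal_grayvol
rh_superiorfrontal_thicknessavg
lh_superiorparietal_surfacearea
lh_superiorparietal_grayvol
lh_superiorparietal_thicknessavg
rh_superiorparietal_surfacearea
rh_superiorparietal_grayvol
rh_superiorparietal_thicknessavg
lh_superiortemporal_surfacearea
lh_superiortemporal_grayvol
lh_superiortemporal_thicknessavg
rh_superiortemporal_surfacearea
rh_superiortemporal_grayvol
rh_superiortemporal_thicknessavg
lh_supramarginal_surfacearea
lh_supramarginal_grayvol
lh_supramarginal_thicknessavg
rh_supramarginal_surfacearea
rh_supramarginal_grayvol
rh_supramarginal_thicknessavg
lh_transversetemporal_surfacearea
lh_transversetemporal_grayvol
lh_transversetemporal_thicknessavg
rh_transversetemporal_surfacearea
rh_transversetemporal_grayvol
rh_transversetemporal_thicknessavg
lh_temporalpole_surfacearea
lh_temporalpole_grayvol
lh_temporalpole_thicknessavg
rh_temporalpole_surfacearea
rh_temporalpole_grayvol
rh_temporalpole_thicknessavg
lh_insula_surfacearea
lh_insula_grayvol
lh_insula_thicknessavg
rh_insula_surfacearea
rh_insula_grayvol
rh_insula_thicknessavg
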