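feature,mmi,direction
fractal_dimension,0.347974,ramified
lacunarity,0.50747,ramified
cell_area_um2,0.464576,amoeboid
convex_hull_area_um2,0.424609,ramified
density,0.513855,amoeboid
cell_perimeter_um,0.430981,ramified
convex_hull_perimeter_um,0.294781,ramified
roughness,0.446389,ramified
convex_hull_circularity,0.543737,amoeboid
cell_circularity,0.600643,amoeboid
total_process_length_um,0.430398,ramified
max_process_length_um,0.314099,ramified
mean_process_length_um,0.207123,ramified
sholl_max_counts,0.378631,ramified
straightness,0.286425,ramified
cell_body_area_um2,0.582923,amoeboid
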