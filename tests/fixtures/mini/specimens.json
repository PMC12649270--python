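{"1": {"specimen_id": 1, "femur": {"name": "femur", "bead_labels": ["f1", "f2", "f3", "f4", "f5", "f6"], "bead_coordinates": [[32.36625661803332, -0.7675994629727168, 67.492588911632], [-19.024315399913576, -6.182730576800449, 59.298902090458775], [-4.35877228625553, -23.625122288125922, 48.57745470330462], [9.954485384348084, -46.21747713660804, 85.07362850764818], [36.0525967856037, -6.1887996709198525, 83.90760583577554], [35.02319752409605, -14.540503968124476, 30.765366245173034]], "landmarks": {"medial_epicondyle": [-38.43174753406515, -13.728932690273092, 23.99440600324805], "lateral_epicondyle": [40.034598867615315, -12.873755974725965, 8.428380333326], "proximal_shaft": [35.88640689054229, -22.68039149891128, 192.55502805987626]}, "bead_diameter_mm": 1.0}, "tibia": {"name": "tibia", "bead_labels": ["t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8"], "bead_coordinates": [[-36.422434741778375, 6.713276208823412, -79.64602563829858], [-4.139393094653656, -24.927960311506148, -51.35464142453984], [-7.352260181935394, -36.81191857954576, -60.34092648280847], [-35.38855433796968, 7.723001175544383, -43.58509635994023], [9.600670819739602, -6.086972115722048, -78.03677686063536], [4.76510450594489, -32.23060211172418, -26.67194912820314], [-4.042898916185495, 5.239493666938973, -49.916204154934825], [-47.489581620998756, -36.746906469025106, -54.76175647215891]], "landmarks": {"medial_plateau": [-53.14427646015221, -11.362943211450197, -5.367498815994504], "lateral_plateau": [16.17135477764037, -21.063402962119252, -6.483001721415438], "distal_shaft": [-24.465652572934992, -30.24084408802554, -255.4777972653581]}, "bead_diameter_mm": 1.0}, "frozen_relative_pose": [[0.9810268703049043, -0.06193727185604923, 0.1837118779360617, 10.196138095135314], [0.1512416515652147, 0.8373512751802988, -0.525327331085823, 1.1364617314392351], [-0.12129403353665326, 0.5431451153319502, 0.830831596124902, -11.562188504573552], [0.0, 0.0, 0.0, 1.0]], "flexion_deg": 25.324682344835427, "soft_tissue_volume_cm3": 3038.0, "noise_scale": 1.0}}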