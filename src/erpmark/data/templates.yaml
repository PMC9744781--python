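# Component templates for the synthetic-EEG generator: one entry per ERP
# component. peak_ms/sd_ms define the Gaussian time course, centers the
# electrodes where the scalp weight is 1 (Gaussian falloff of
# spatial_sigma head-disc units elsewhere), amplitude the signed category
# peak in microvolt. Edit amplitudes freely: the ordering validator
# (erpmark.simulate.validate_template_orderings) checks that every marker
# contrast still holds on the noiseless evoked responses.
N170_left:
  modality: visual
  peak_ms: 170
  sd_ms: 15
  centers: [PPO9h, P7]
  amplitude:
    adult_face: -7
    infant_face: -7
    animal_face: -4
    body: -5
    word_visual: -8
    checkerboard: -5
    object: -2
N170_right:
  modality: visual
  peak_ms: 170
  sd_ms: 15
  centers: [PPO10h, P8]
  amplitude:
    adult_face: -7
    infant_face: -7
    animal_face: -4
    body: -5
    word_visual: -3.5
    checkerboard: -3.5
    object: -3.5
N2:
  modality: visual
  peak_ms: 300
  sd_ms: 35
  centers: [AFp3h, AFp4h, Fpz, CPz, Cz]
  amplitude:
    infant_face: -6
    adult_face: -4
    animal_face: -4
    body: -2
    word_visual: -1.5
    checkerboard: -1.5
    object: -1.5
P2_visual:
  modality: visual
  peak_ms: 325
  sd_ms: 25
  centers: [CPz, Pz]
  amplitude:
    body: 6
    animal_face: 4
    adult_face: 2.5
    infant_face: 2.5
    word_visual: 1.5
    checkerboard: 1.5
    object: 1.5
P300_visual:
  modality: visual
  peak_ms: 500
  sd_ms: 55
  centers: [AFz, Fz]
  amplitude:
    animal_face: 6
    infant_face: 4
    body: 3
    adult_face: 2.5
    word_visual: 2
    checkerboard: 2
    object: 2
CPP:
  modality: visual
  peak_ms: 500
  sd_ms: 55
  centers: [CPz, Pz]
  amplitude:
    infant_face: 5
    animal_face: 4.5
    adult_face: 4
    body: 3
    word_visual: 2
    checkerboard: 2
    object: 2
LCPP:
  modality: visual
  peak_ms: 750
  sd_ms: 80
  centers: [CPz, Pz]
  amplitude:
    infant_face: 4.5
    animal_face: 3.5
    adult_face: 3
    body: 2.5
    word_visual: 2
    checkerboard: 2
    object: 2
AN_visual:
  modality: visual
  peak_ms: 380
  sd_ms: 80
  centers: [AFp3h, AFp4h, AFz, Fpz, Fz]
  amplitude:
    infant_face: -6
    adult_face: -4.5
    animal_face: -2.5
    body: -2.5
    word_visual: -2
    checkerboard: -2
    object: -2
AP:
  modality: visual
  peak_ms: 700
  sd_ms: 45
  centers: [AFz, Fz]
  amplitude:
    animal_face: 4
    infant_face: 2
    body: 2
    adult_face: 1.5
    word_visual: 1.5
    checkerboard: 1.5
    object: 1.5
N80:
  modality: visual
  peak_ms: 110
  sd_ms: 12
  centers: [Oz, Iz]
  spatial_sigma: 0.15
  amplitude:
    checkerboard: -6
    word_visual: -3
    object: -2
    adult_face: -3
    infant_face: -3
    animal_face: -3
    body: -3
P2_auditory:
  modality: auditory
  peak_ms: 220
  sd_ms: 40
  centers: [FFC1h, FFC2h, C1, C2]
  amplitude:
    vocalization: 6
    word_auditory: 5
    music: 3
P300_auditory:
  modality: auditory
  peak_ms: 450
  sd_ms: 40
  centers: [FFC1h, FFC2h, C1, C2]
  amplitude:
    music: 6
    word_auditory: 3.5
    vocalization: 3
N400_auditory:
  modality: auditory
  peak_ms: 550
  sd_ms: 55
  centers: [CCP1h, CCP2h, P3, P4]
  amplitude:
    word_auditory: -6
    vocalization: -4
    music: -3
AN_auditory:
  modality: auditory
  peak_ms: 500
  sd_ms: 55
  centers: [AF3, AF4, AF7, AF8]
  amplitude:
    vocalization: -6
    word_auditory: -3.5
    music: -3
LP:
  modality: auditory
  peak_ms: 1050
  sd_ms: 80
  centers: [AF3, AF4, AF7, AF8]
  amplitude:
    vocalization: 6
    word_auditory: 5
    music: 3
PN300:
  modality: both
  peak_ms: 300
  sd_ms: 45
  centers: [Fz, Cz]
  amplitude:
    infant_face: -4
    adult_face: -4
    animal_face: -4
    body: -4
    word_visual: -4
    checkerboard: -4
    object: -4
    word_auditory: 4
    vocalization: 4
    music: 4
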