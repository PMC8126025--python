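# Default compartment mobility templates on the pooled-sample axis (1-48).
# Each compartment is a 1- or 2-component Gaussian mixture; centers/widths
# are in pooled-sample units, weights are mass fractions summing to 1.
#
# Windows they encode (anodic -> cathodic):
#   TP            major population samples 13-19, minor population at 24
#   ER            two populations, 18-20 and 23-25
#   GA            samples 23-24
#   TGN           concentrated in single sample 24
#   Chl-envelope  samples 23-25
#   TLK           high abundance at sample 20 plus 23-24 population
#   MT            low abundance at sample 20 plus 23-24 population
#   PM            samples 24-30 with peak of abundance at sample 25
templates:
  - name: TP
    peaks:
      - {center: 16.0, width: 1.6, weight: 0.75}
      - {center: 24.0, width: 0.7, weight: 0.25}
  - name: ER
    peaks:
      - {center: 19.0, width: 0.8, weight: 0.45}
      - {center: 24.0, width: 0.9, weight: 0.55}
  - name: GA
    peaks:
      - {center: 23.3, width: 0.55, weight: 1.0}
  - name: TGN
    peaks:
      - {center: 24.0, width: 0.4, weight: 1.0}
  - name: Chl-envelope
    peaks:
      - {center: 24.0, width: 1.15, weight: 1.0}
  - name: TLK
    peaks:
      - {center: 20.0, width: 0.4, weight: 0.45}
      - {center: 23.3, width: 0.55, weight: 0.55}
  - name: MT
    peaks:
      - {center: 20.0, width: 0.4, weight: 0.25}
      - {center: 24.2, width: 1.0, weight: 0.75}
  - name: PM
    peaks:
      - {center: 25.2, width: 1.1, weight: 1.0}
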