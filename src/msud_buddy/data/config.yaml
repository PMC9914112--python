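# Operational configuration for plan construction.  Everything here is
# overridable by a user-supplied config file.
#
# scoop_grams: mass of one scoop of powder (the dosing unit).
# *_tolerance: fractional band around the protein/energy targets beyond
#   which the plan raises a warning flag.
# feeds_per_day_by_band: number of feeds across which the daily scoops and
#   water are split, per age band (months 1..6).
# plasma_bands: therapeutic plasma targets (umol/L) used only by the
#   default adjustment rules.  NON-AUTHORITATIVE defaults: treating
#   clinicians must supply centre-specific targets.
scoop_grams: 5.0
protein_tolerance: 0.10
energy_tolerance: 0.10
feeds_per_day_by_band:
  1: 8
  2: 8
  3: 8
  4: 6
  5: 6
  6: 6
plasma_bands:
  leucine: {low_max: 75, high_min: 200}
  isoleucine: {low_max: 200, high_min: 400}
  valine: {low_max: 200, high_min: 400}
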