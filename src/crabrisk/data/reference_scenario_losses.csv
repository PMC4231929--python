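# Published scenario outcomes for green-crab predation on the Puget Sound
# shellfish harvest: change from baseline per species group and per 3x3
# (calorie diet x invasion density) scenario cell. Used to back-solve the
# unpublished per-crab annual calorie-intake levels (species rows, kg only)
# and to propagate published revenue-loss fractions into the economic cascade
# ('all' rows carry the published total kg and USD changes).
# A floored cell means the published post-invasion harvest is 0 (consumption
# reached the baseline); it censors the loss and is excluded from calibration.
species_group,calorie_level,density_level,loss_kg,loss_usd,floored
hardshell_clam,low,low,10000,,False
hardshell_clam,low,medium,10000,,False
hardshell_clam,low,high,70000,,False
hardshell_clam,medium,low,110000,,False
hardshell_clam,medium,medium,170000,,False
hardshell_clam,medium,high,1130000,,False
hardshell_clam,high,low,210000,,False
hardshell_clam,high,medium,300000,,False
hardshell_clam,high,high,2040000,,False
oyster,low,low,20000,,False
oyster,low,medium,20000,,False
oyster,low,high,30000,,False
oyster,medium,low,40000,,False
oyster,medium,medium,210000,,False
oyster,medium,high,420000,,False
oyster,high,low,80000,,False
oyster,high,medium,380000,,False
oyster,high,high,760000,,False
mussel,low,low,10000,,False
mussel,low,medium,10000,,False
mussel,low,high,60000,,False
mussel,medium,low,90000,,False
mussel,medium,medium,170000,,False
mussel,medium,high,900000,,False
mussel,high,low,170000,,False
mussel,high,medium,310000,,False
mussel,high,high,1290000,,True
all,low,low,40000,80000,False
all,low,medium,40000,230000,False
all,low,high,150000,1030000,False
all,medium,low,240000,1390000,False
all,medium,medium,540000,3720000,False
all,medium,high,2450000,13830000,False
all,high,low,450000,2520000,False
all,high,medium,990000,6760000,False
all,high,high,4460000,23800000,False
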