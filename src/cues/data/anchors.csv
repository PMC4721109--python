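# Default anchor-city annual UV index table.
# Only the four cities whose average annual UV indices are published in the
# study report are shipped; supply the full 58-city table via the same schema
# to reproduce the original coverage. Coordinates are taken from the packaged
# gazetteer (approximate public city coordinates, not study data).
name,state,latitude,longitude,annual_uvi
Anchorage,AK,61.2181,-149.9003,1.9
Seattle,WA,47.6062,-122.3321,3.3
Honolulu,HI,21.3069,-157.8583,9.3
San Juan,PR,18.4655,-66.1057,10.3
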