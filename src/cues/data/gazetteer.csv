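# Offline gazetteer: approximate coordinates for US cities used to resolve
# "City, State" residence strings without a network geocoder. Coordinates are
# public approximate city-center values (not study data).
city,state,latitude,longitude
Anchorage,AK,61.2181,-149.9003
Fairbanks,AK,64.8378,-147.7164
Phoenix,AZ,33.4484,-112.0740
Los Angeles,CA,34.0522,-118.2437
San Diego,CA,32.7157,-117.1611
San Francisco,CA,37.7749,-122.4194
Denver,CO,39.7392,-104.9903
Hartford,CT,41.7658,-72.6734
Washington,DC,38.9072,-77.0369
Jacksonville,FL,30.3322,-81.6557
Miami,FL,25.7617,-80.1918
Tampa,FL,27.9506,-82.4572
Atlanta,GA,33.7490,-84.3880
Honolulu,HI,21.3069,-157.8583
Boise,ID,43.6150,-116.2023
Chicago,IL,41.8781,-87.6298
Indianapolis,IN,39.7684,-86.1581
New Orleans,LA,29.9511,-90.0715
Boston,MA,42.3601,-71.0589
Baltimore,MD,39.2904,-76.6122
Portland,ME,43.6591,-70.2568
Detroit,MI,42.3314,-83.0458
Minneapolis,MN,44.9778,-93.2650
Kansas City,MO,39.0997,-94.5786
St. Louis,MO,38.6270,-90.1994
Charlotte,NC,35.2271,-80.8431
Raleigh,NC,35.7796,-78.6382
Omaha,NE,41.2565,-95.9345
Albuquerque,NM,35.0844,-106.6504
Las Vegas,NV,36.1699,-115.1398
Buffalo,NY,42.8864,-78.8784
New York,NY,40.7128,-74.0060
Cleveland,OH,41.4993,-81.6944
Columbus,OH,39.9612,-82.9988
Oklahoma City,OK,35.4676,-97.5164
Portland,OR,45.5152,-122.6784
Philadelphia,PA,39.9526,-75.1652
Pittsburgh,PA,40.4406,-79.9959
San Juan,PR,18.4655,-66.1057
Providence,RI,41.8240,-71.4128
Memphis,TN,35.1495,-90.0490
Nashville,TN,36.1627,-86.7816
Austin,TX,30.2672,-97.7431
Dallas,TX,32.7767,-96.7970
Houston,TX,29.7604,-95.3698
Salt Lake City,UT,40.7608,-111.8910
Richmond,VA,37.5407,-77.4360
Burlington,VT,44.4759,-73.2121
Seattle,WA,47.6062,-122.3321
Milwaukee,WI,43.0389,-87.9065
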