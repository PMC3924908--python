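participant,gender,age,description,stage,ear,stimulus_class,frequency_hz,band_low_hz,band_high_hz,f_avg_hz,level_db_spl,similarity_0_10,duration_min
1,M,51,"Squeal, in the head",I,right,tone,6000,,,,65,7,4
1,M,51,"Squeal, in the head",I,left,tone,4000,,,,59.5,7,4
1,M,51,"Squeal, in the head",II,right,tone,2724,,,,35.5,9,2
1,M,51,"Squeal, in the head",II,left,tone,2655,,,,32.4,9,2
2,M,67,"High whistle, in LE and RE",I,right,tone,4000,,,,34.5,6,6
2,M,67,"High whistle, in LE and RE",I,left,tone,4000,,,,34.5,6,6
2,M,67,"High whistle, in LE and RE",II,right,tone,6172,,,,79,9,2
2,M,67,"High whistle, in LE and RE",II,left,tone,6251,,,,76.7,9,2
3,M,77,"Hum of bees, in the head",I,right,tone,3000,,,,70,3,4
3,M,77,"Hum of bees, in the head",I,left,tone,3000,,,,75,3,4
3,M,77,"Hum of bees, in the head",II,right,tone,1929,,,,56.7,8,2
3,M,77,"Hum of bees, in the head",II,left,tone,1954,,,,57.3,8,2
4,F,79,"Low-frequency hum and squeal, in LE",I,left,tone,2000,,,,49,2,5
4,F,79,"Low-frequency hum and squeal, in LE",II,left,tone,82,,,,88.4,9,4
4,F,79,"Low-frequency hum and squeal, in LE",II,left,tone,361,,,,65.5,9,4
4,F,79,"Low-frequency hum and squeal, in LE",II,left,tone,1281,,,,39,9,4
5,M,36,"Squeal, in RE",I,right,tone,4000,,,,79.5,3,8
5,M,36,"Squeal, in RE",II,right,tone,5572,,,,72,3,6
6,F,61,"Murmur, squeal, in RE and LE",I,right,tone,8000,,,,68,6,10
6,F,61,"Murmur, squeal, in RE and LE",I,left,tone,8000,,,,63,6,10
6,F,61,"Murmur, squeal, in RE and LE",II,left,noise,,8900,10400,9682,44.5,9,8
7,F,61,"High metallic sound",I,right,tone,8000,,,,33,7,6
7,F,61,"High metallic sound",I,left,tone,8000,,,,43,7,6
7,F,61,"High metallic sound",II,right,tone,7103,,,,37.2,9,2
7,F,61,"High metallic sound",II,left,tone,7103,,,,44.9,9,2
8,F,65,"Constant noise in head",I,left,narrowband,1000,,,,38,9,6
8,F,65,"Constant noise in head",II,left,noise,,350,2100,1229,31.6,10,1
9,M,42,"Squeal",I,right,tone,4000,,,,59.5,8,5
9,M,42,"Squeal",I,left,tone,3000,,,,60,8,5
9,M,42,"Squeal",II,right,tone,3216,,,,61.5,8,2
9,M,42,"Squeal",II,left,tone,3216,,,,61.5,8,2
10,F,61,"Constant noise in RE",I,right,narrowband,2000,,,,86,8,3
10,F,61,"Constant noise in RE",II,right,noise,,900,2400,1655,52.2,5,4
11,F,37,"Squeal or hiss in LE",I,left,tone,3000,,,,35,5,3
11,F,37,"Squeal or hiss in LE",II,left,tone,2398,,,,32.7,5,2
12,F,37,"Squeal or hiss in LE",I,left,narrowband,6000,,,,25,7,5
12,F,37,"Squeal or hiss in LE",II,left,noise,,6200,6600,6424,22.1,8,3
13,M,24,"High squeal or noise of working TV in head",I,right,tone,6000,,,,20,7,9
13,M,24,"High squeal or noise of working TV in head",I,left,tone,6000,,,,30,7,9
13,M,24,"High squeal or noise of working TV in head",II,right,tone,6093,,,,28,8,4
13,M,24,"High squeal or noise of working TV in head",II,left,tone,6093,,,,38.7,8,4
14,M,24,"High squeal or noise of working TV in head",I,right,narrowband,6000,,,,20,1,2
14,M,24,"High squeal or noise of working TV in head",I,left,narrowband,6000,,,,35,1,2
14,M,24,"High squeal or noise of working TV in head",II,right,noise,,3600,6100,4874,14.3,9,6
14,M,24,"High squeal or noise of working TV in head",II,left,noise,,3600,6100,4874,28.2,9,6
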