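# synthetic stand-in for the unpublished per-reach survey data:
# per-reach dam counts whose site, category and total tallies match
# the published survey summary (89 dams in 58 reaches).
aoi,category,reach_id,dams
Tay,Rare,R000,1
Tay,Rare,R001,1
Tay,Rare,R002,1
Tay,Rare,R003,1
Tay,Rare,R004,1
Tay,Rare,R005,1
Tay,Occasional,R006,2
Tay,Occasional,R007,2
Tay,Occasional,R008,1
Tay,Occasional,R009,1
Tay,Occasional,R010,1
Tay,Occasional,R011,1
Tay,Frequent,R012,2
Tay,Frequent,R013,2
Tay,Frequent,R014,2
Tay,Frequent,R015,1
Tay,Frequent,R016,1
Tay,Pervasive,R017,3
Tay,Pervasive,R018,3
Tay,Pervasive,R019,3
Tay,Pervasive,R020,2
Tay,Pervasive,R021,2
Tay,Pervasive,R022,2
Tay,Pervasive,R023,2
Tay,Pervasive,R024,2
Otter,Rare,R025,2
Otter,Rare,R026,1
Otter,Rare,R027,1
Otter,Occasional,R028,2
Otter,Occasional,R029,1
Otter,Occasional,R030,1
Otter,Occasional,R031,1
Otter,Frequent,R032,2
Otter,Frequent,R033,2
Otter,Frequent,R034,2
Otter,Frequent,R035,2
Otter,Frequent,R036,2
Otter,Frequent,R037,1
Otter,Frequent,R038,1
Otter,Frequent,R039,1
Otter,Frequent,R040,1
Otter,Pervasive,R041,2
Otter,Pervasive,R042,2
Otter,Pervasive,R043,2
Otter,Pervasive,R044,2
Otter,Pervasive,R045,1
Otter,Pervasive,R046,1
Otter,Pervasive,R047,1
Otter,Pervasive,R048,1
Coombeshead,Pervasive,R049,2
Coombeshead,Pervasive,R050,2
Coombeshead,Pervasive,R051,2
Coombeshead,Pervasive,R052,2
Coombeshead,Pervasive,R053,1
Coombeshead,Pervasive,R054,1
Coombeshead,Pervasive,R055,1
Coombeshead,Pervasive,R056,1
Coombeshead,Pervasive,R057,1
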