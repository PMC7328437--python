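group,activity,metric,value,tolerance,kind
commuter,shop_food,participation,27.0,3.0,abs
commuter,shop_food,duration_mean,41.0,0.15,rel
commuter,shop_food,duration_median,30.0,0.15,rel
retired,shop_food,participation,49.0,3.0,abs
retired,shop_food,duration_mean,69.0,0.15,rel
retired,shop_food,duration_median,50.0,0.15,rel
commuter,sports,participation,16.2,3.0,abs
retired,sports,participation,17.8,3.0,abs
commuter,lunch_out,participation,4.5,3.0,abs
commuter,evening_social,participation,7.9,3.0,abs
retired,lunch_out,participation,7.9,3.0,abs
retired,evening_social,participation,7.9,3.0,abs
retired,shop_leisure,participation,16.6,3.0,abs
commuter,work,duration_mean,480.0,30.0,abs
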