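wavelength_nm,eps_hbo,eps_hhb
450.0,62816.0,60000.0
451.0,59152.8,56080.2
452.0,55604.5,52289.8
453.0,52186.4,48656.8
454.0,48914.1,45209.3
455.0,45803.1,41975.7
456.0,42869.0,38984.0
457.0,40127.0,36262.4
458.0,37592.9,33839.1
459.0,35282.1,31742.2
460.0,33210.0,30000.0
461.0,31284.3,28491.6
462.0,29414.7,27079.1
463.0,27619.6,25764.6
464.0,25917.6,24550.5
465.0,24327.4,23439.0
466.0,22867.3,22432.4
467.0,21556.0,21533.0
468.0,20412.0,20742.9
469.0,19453.8,20064.5
470.0,18700.0,19500.0
471.0,18061.0,19001.8
472.0,17442.3,18524.7
473.0,16854.9,18074.5
474.0,16309.8,17656.9
475.0,15818.2,17277.8
476.0,15391.2,16942.8
477.0,15039.8,16657.7
478.0,14775.1,16428.4
479.0,14608.1,16260.6
480.0,14550.0,16160.0
481.0,14633.7,16097.3
482.0,14865.0,16039.4
483.0,15214.6,15986.7
484.0,15653.0,15939.7
485.0,16150.8,15898.8
486.0,16678.5,15864.3
487.0,17206.7,15836.8
488.0,17706.0,15816.6
489.0,18146.9,15804.2
490.0,18500.0,15800.0
491.0,18786.5,15902.6
492.0,19050.5,16187.5
493.0,19296.7,16620.1
494.0,19529.6,17166.0
495.0,19753.9,17790.7
496.0,19974.3,18459.8
497.0,20195.5,19138.7
498.0,20422.0,19793.1
499.0,20658.7,20388.3
500.0,20910.0,20890.0
501.0,21172.2,21307.2
502.0,21439.8,21689.8
503.0,21715.4,22064.9
504.0,22001.3,22459.3
505.0,22300.0,22900.0
506.0,22611.5,23417.2
507.0,22935.5,23999.0
508.0,23273.8,24609.3
509.0,23628.0,25211.7
510.0,24000.0,25770.0
511.0,24380.2,26276.1
512.0,24761.5,26751.7
513.0,25149.4,27205.4
514.0,25549.1,27646.0
515.0,25966.2,28082.2
516.0,26405.9,28522.6
517.0,26873.8,28975.8
518.0,27375.2,29450.7
519.0,27915.4,29955.9
520.0,28500.0,30500.0
521.0,29155.2,31090.4
522.0,29897.9,31724.1
523.0,30719.1,32394.2
524.0,31610.1,33094.0
525.0,32561.8,33816.8
526.0,33565.5,34555.6
527.0,34612.1,35303.8
528.0,35692.9,36054.5
529.0,36799.0,36801.0
530.0,38005.3,37550.9
531.0,39353.8,38315.5
532.0,40786.0,39093.9
533.0,42243.5,39884.9
534.0,43667.6,40687.3
535.0,45000.0,41500.0
536.0,46387.1,42325.2
537.0,47925.7,43164.2
538.0,49482.7,44015.3
539.0,50925.3,44876.4
540.0,52120.4,45745.5
541.0,52934.9,46620.7
542.0,53236.0,47500.0
543.0,52709.2,48481.9
544.0,51508.1,49476.4
545.0,50201.0,50199.0
546.0,48913.9,50661.4
547.0,47456.7,51060.2
548.0,45924.6,51387.9
549.0,44412.7,51636.9
550.0,43016.0,51800.0
551.0,41718.3,51912.7
552.0,40452.0,52011.4
553.0,39234.9,52089.7
554.0,38084.9,52141.4
555.0,37020.0,52160.0
556.0,35910.8,52131.6
557.0,34735.9,52052.5
558.0,33674.4,51931.5
559.0,32906.0,51777.7
560.0,32610.0,51600.0
561.0,32736.4,51297.9
562.0,33084.7,50805.7
563.0,33608.8,50184.6
564.0,34262.6,49495.7
565.0,35000.0,48800.0
566.0,36121.7,48052.6
567.0,37828.5,47199.8
568.0,39924.1,46290.3
569.0,42212.3,45372.6
570.0,44497.0,44495.0
571.0,46943.1,43668.6
572.0,49677.6,42857.9
573.0,52447.6,42042.0
574.0,55000.0,41200.0
575.0,57728.6,40316.9
576.0,60324.3,39408.4
577.0,61480.0,38500.0
578.0,59881.3,37616.8
579.0,56175.9,36733.7
580.0,52000.0,35800.0
581.0,47479.6,34754.2
582.0,42103.1,33628.4
583.0,36550.3,32513.2
584.0,31501.0,31499.0
585.0,26848.1,30626.0
586.0,22289.1,29829.6
587.0,18210.8,29043.1
588.0,15000.0,28200.0
589.0,12484.8,27295.2
590.0,10291.0,26355.7
591.0,8501.7,25363.4
592.0,7200.0,24300.0
593.0,6261.8,23106.3
594.0,5494.9,21796.8
595.0,4880.6,20463.9
596.0,4400.0,19200.0
597.0,4018.5,17960.7
598.0,3702.7,16716.8
599.0,3435.6,15583.8
600.0,3200.0,14677.0
601.0,2977.5,13952.6
602.0,2762.3,13286.3
603.0,2555.9,12673.2
604.0,2360.2,12108.1
605.0,2176.9,11585.9
606.0,2007.7,11101.7
607.0,1854.2,10650.4
608.0,1718.3,10226.9
609.0,1601.7,9826.1
610.0,1506.0,9443.0
611.0,1425.4,9073.1
612.0,1352.4,8716.3
613.0,1286.1,8374.0
614.0,1225.7,8047.7
615.0,1170.5,7739.0
616.0,1119.5,7449.3
617.0,1072.0,7180.0
618.0,1027.1,6932.7
619.0,984.0,6708.9
620.0,942.0,6510.0
621.0,900.9,6330.4
622.0,861.1,6162.8
623.0,822.9,6006.4
624.0,786.4,5860.2
625.0,751.6,5723.4
626.0,718.9,5595.1
627.0,688.2,5474.4
628.0,659.7,5360.4
629.0,633.6,5252.3
630.0,610.0,5149.0
631.0,588.1,5050.8
632.0,567.3,4957.9
633.0,547.4,4869.8
634.0,528.6,4786.1
635.0,511.0,4706.1
636.0,494.5,4629.4
637.0,479.3,4555.5
638.0,465.5,4483.8
639.0,453.0,4413.8
640.0,442.0,4345.0
641.0,432.1,4278.0
642.0,423.0,4213.4
643.0,414.6,4151.0
644.0,406.7,4090.5
645.0,399.4,4031.6
646.0,392.6,3973.9
647.0,386.1,3917.3
648.0,379.9,3861.3
649.0,373.9,3805.6
650.0,368.0,3750.0
651.0,362.2,3694.5
652.0,356.6,3639.5
653.0,351.2,3585.0
654.0,346.0,3531.2
655.0,340.9,3478.1
656.0,336.2,3425.8
657.0,331.7,3374.5
658.0,327.4,3324.1
659.0,323.6,3275.0
660.0,320.0,3227.0
661.0,316.7,3180.3
662.0,313.6,3134.6
663.0,310.7,3089.9
664.0,308.0,3046.0
665.0,305.4,3002.9
666.0,302.9,2960.4
667.0,300.5,2918.5
668.0,298.3,2877.0
669.0,296.1,2835.9
670.0,294.0,2795.0
671.0,291.9,2754.4
672.0,289.6,2714.4
673.0,287.3,2674.8
674.0,285.1,2635.6
675.0,282.9,2596.9
676.0,281.0,2558.5
677.0,279.4,2520.5
678.0,278.1,2482.7
679.0,277.3,2445.2
680.0,277.0,2408.0
681.0,277.0,2370.6
682.0,277.2,2332.9
683.0,277.4,2295.1
684.0,277.6,2257.5
685.0,277.9,2220.4
686.0,278.3,2184.0
687.0,278.7,2148.6
688.0,279.1,2114.5
689.0,279.5,2081.9
690.0,280.0,2051.0
691.0,280.5,2021.5
692.0,281.2,1992.6
693.0,282.0,1964.6
694.0,282.9,1937.4
695.0,283.9,1911.0
696.0,285.0,1885.6
697.0,286.1,1861.1
698.0,287.4,1837.7
699.0,288.7,1815.3
700.0,290.0,1794.0
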